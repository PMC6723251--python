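# Bundled viral-polymerase alignment-tree configuration.
#
# The tree starts from the minimal shared core of the four polymerase classes
# (DdDP family A/B, DdRP, RdDP, RdRP) and grows the aligned region as
# similarity increases: 13 columns of motifs A+C at the root, 40 columns after
# adding motif F for the RdRPs, 65 after adding motif B for the positive-strand
# RNA virus enzymes, and complete structures within single virus families.
# The opcl set bridges the open and closed active-site conformations of the
# positive-strand RdRPs using full structures: its orientation arrives through
# a closed-form EV71 polymerase (5F8J) and the matching open-form structure
# (5F8G) seeds all subsequent positive-strand sets.
#
# Column ranges within each motif are curator-supplied (1-based, inclusive,
# in alignment coordinates of each set's alignment).  Member entries whose PDB
# ids are not fixed by the published description are placeholders and
# curator-editable, as are all member file paths (structures are not bundled;
# fetch them from the PDB into pdbs/ before running).
sets:
  - name: pols
    prefix: "1"
    parent: ROOT
    seed: {pdb: 1t7p, chain: A}
    alignment: auto
    region:
      motif_A: [[101, 107]]   # 7 columns
      motif_C: [[201, 206]]   # 6 columns -> 13 total
    members:
      - {pdb: 1t7p, chain: A, file: pdbs/1t7p.pdb, representative: DDDA}  # T7 DNA polymerase (family A)
      - {pdb: 1ig9, chain: A, file: pdbs/1ig9.pdb, representative: DDDB}  # RB69 polymerase (family B)
      - {pdb: 1msw, chain: D, file: pdbs/1msw.pdb, representative: DDRP}  # T7 RNA polymerase
      - {pdb: 1rtd, chain: A, file: pdbs/1rtd.pdb, representative: RDDP}  # HIV-1 reverse transcriptase
      - {pdb: 1rdr, chain: A, file: pdbs/1rdr.pdb, representative: RDRP}  # poliovirus 3Dpol (placeholder choice)

  - name: rdrp
    prefix: "2"
    parent: pols
    seed: {pdb: 1rdr, chain: A}
    alignment: auto
    region:
      motif_F: [[60, 73]]     # 14 columns
      motif_A: [[95, 107]]    # 13 columns
      motif_C: [[195, 207]]   # 13 columns -> 40 total
    members:
      - {pdb: 1rdr, chain: A, file: pdbs/1rdr.pdb}
      - {pdb: 5f8j, chain: A, file: pdbs/5f8j.pdb, representative: PSRN}  # EV71 3Dpol, closed active site
      - {pdb: 4wsb, chain: A, file: pdbs/4wsb.pdb, representative: NSRN}  # negative-strand rep (placeholder)
      - {pdb: 1hhs, chain: A, file: pdbs/1hhs.pdb, representative: DSRN}  # phi6 RdRP, dsRNA rep (placeholder)

  - name: qbta
    parent: pols
    seed: {pdb: 1rdr, chain: A}
    alignment: auto
    region:
      motif_F: [[60, 73]]
      motif_A: [[95, 107]]
      motif_C: [[195, 207]]
    members:
      - {pdb: 1rdr, chain: A, file: pdbs/1rdr.pdb}
      - {pdb: 3mmp, chain: A, file: pdbs/3mmp.pdb}  # Qbeta replicase (placeholder)
      - {pdb: 4q7j, chain: A, file: pdbs/4q7j.pdb}  # Qbeta replicase (placeholder)

  # Open/closed pivot: full structures, two open/closed pairs each of
  # poliovirus and EV71 solved from identical crystals.  Orientation arrives
  # via closed 5F8J; children seed from open 5F8G.
  - name: opcl
    parent: rdrp
    seed: {pdb: 5f8j, chain: A}
    alignment: auto
    region: FULL
    members:
      - {pdb: 5f8j, chain: A, file: pdbs/5f8j.pdb}  # EV71, closed
      - {pdb: 5f8g, chain: A, file: pdbs/5f8g.pdb}  # EV71, open
      - {pdb: 5f8h, chain: A, file: pdbs/5f8h.pdb}  # EV71 second pair (placeholder)
      - {pdb: 5f8l, chain: A, file: pdbs/5f8l.pdb}  # EV71 second pair (placeholder)
      - {pdb: 3ol6, chain: A, file: pdbs/3ol6.pdb}  # poliovirus, open (placeholder)
      - {pdb: 3ol7, chain: A, file: pdbs/3ol7.pdb}  # poliovirus, closed (placeholder)
      - {pdb: 3ola, chain: A, file: pdbs/3ola.pdb}  # poliovirus second pair (placeholder)
      - {pdb: 3olb, chain: A, file: pdbs/3olb.pdb}  # poliovirus second pair (placeholder)

  - name: psrn
    prefix: "3"
    parent: opcl
    seed: {pdb: 5f8g, chain: A}
    alignment: auto
    region:
      motif_F: [[60, 73]]
      motif_A: [[95, 107]]
      motif_B: [[150, 174]]   # 25 columns -> 65 total
      motif_C: [[195, 207]]
    members:
      - {pdb: 5f8g, chain: A, file: pdbs/5f8g.pdb, representative: PICO}
      - {pdb: 1sh0, chain: A, file: pdbs/1sh0.pdb, representative: CALI}  # norovirus pol
      - {pdb: 6nur, chain: A, file: pdbs/6nur.pdb, representative: CORO}  # coronavirus nsp12 (placeholder)
      - {pdb: 5tmh, chain: A, file: pdbs/5tmh.pdb, representative: FLAV}  # zika NS5
      - {pdb: 2xi2, chain: A, file: pdbs/2xi2.pdb, representative: HEPC}  # HCV NS5B
      - {pdb: 4xhi, chain: A, file: pdbs/4xhi.pdb, representative: TAVP}  # Thosea asigna (placeholder)

  - name: pico
    prefix: "4"
    parent: psrn
    seed: {pdb: 5f8g, chain: A}
    alignment: sav/pico_v5.aln   # manually curated structure-based alignment
    region: FULL
    members:
      - {pdb: 5f8g, chain: A, file: pdbs/5f8g.pdb, representative: ENTV}
      - {pdb: 4nz0, chain: A, file: pdbs/4nz0.pdb, representative: EMCV}  # EMCV (placeholder)
      - {pdb: 1u09, chain: A, file: pdbs/1u09.pdb, representative: FMDV}  # FMDV 3D

  - name: entv
    parent: pico
    seed: {pdb: 5f8g, chain: A}
    alignment: sav/pico_v5.aln
    region: FULL
    members:
      - {pdb: 5f8g, chain: A, file: pdbs/5f8g.pdb}
      - {pdb: 3ol7, chain: A, file: pdbs/3ol7.pdb}  # poliovirus
      - {pdb: 5xe0, chain: A, file: pdbs/5xe0.pdb}  # EV-D68
      - {pdb: 5y6z, chain: A, file: pdbs/5y6z.pdb}  # coxsackievirus A16
      - {pdb: 3ddk, chain: A, file: pdbs/3ddk.pdb}  # coxsackievirus B3 (placeholder)
      - {pdb: 1xr7, chain: A, file: pdbs/1xr7.pdb}  # rhinovirus (placeholder)

  - name: flav
    parent: psrn
    seed: {pdb: 5tmh, chain: A}
    alignment: auto
    region: FULL
    members:
      - {pdb: 5tmh, chain: A, file: pdbs/5tmh.pdb}  # zika
      - {pdb: 5jjr, chain: A, file: pdbs/5jjr.pdb}  # dengue
      - {pdb: 4k6m, chain: A, file: pdbs/4k6m.pdb}  # JEV
      - {pdb: 2hfz, chain: A, file: pdbs/2hfz.pdb}  # West Nile

  - name: nsrn
    parent: rdrp
    seed: {pdb: 4wsb, chain: A}
    alignment: auto
    region: FULL
    members:
      - {pdb: 4wsb, chain: A, file: pdbs/4wsb.pdb}
      - {pdb: 5amq, chain: A, file: pdbs/5amq.pdb}  # La Crosse virus L (placeholder)

  - name: fluv
    parent: nsrn
    seed: {pdb: 4wsb, chain: A}
    alignment: auto
    region: FULL
    members:
      - {pdb: 4wsb, chain: A, file: pdbs/4wsb.pdb}
      - {pdb: 5d98, chain: B, file: pdbs/5d98.pdb}  # influenza C PB1, first copy
      - {pdb: 5d98, chain: E, file: pdbs/5d98.pdb}  # influenza C PB1, second copy

  - name: poli
    parent: entv
    seed: {pdb: 3ol7, chain: A}
    alignment: auto
    region: FULL
    members:
      - {pdb: 3ol7, chain: A, file: pdbs/3ol7.pdb}
      - {pdb: 1rdr, chain: A, file: pdbs/1rdr.pdb}

  - name: ev71
    parent: entv
    seed: {pdb: 5f8g, chain: A}
    alignment: auto
    region: FULL
    members:
      - {pdb: 5f8g, chain: A, file: pdbs/5f8g.pdb}
      - {pdb: 5f8j, chain: A, file: pdbs/5f8j.pdb}
      - {pdb: 5y6z, chain: A, file: pdbs/5y6z.pdb}
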