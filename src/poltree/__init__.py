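"""poltree: hierarchical maximum-likelihood superposition of viral polymerase
structures, with spatial analyses of the superposed collection.

The package aligns families of polymerase structures through a tree of
superposition sets: each set runs a maximum-likelihood multiple structure
superposition over its own residue-equivalent Cα columns, then re-anchors the
family so its seed structure retains the orientation inherited from the parent
set.  Executing the tree places every structure into one common coordinate
frame, in which fixed anchor points select catalytic aspartates, active-site
metal ions, and monomer neighbourhoods across the whole collection.
"""

from .analysis import (
    AnchorPoint,
    DDRecord,
    DDSurvey,
    IonSiteModel,
    NoActiveSiteError,
    assign_ion_sites,
    dd_distance,
    locate_catalytic_aspartates,
    pool_ions,
    select_within,
    survey_dd,
    trim_to_monomer,
)
from .msa import (
    CorrespondenceTable,
    MotifRegionSet,
    SequenceAlignment,
    build_correspondence,
    pairwise_align,
    parse_alignment,
    progressive_msa,
    restrict_regions,
    write_alignment,
)
from .pdbio import (
    AtomRecord,
    CaTrace,
    IonRecord,
    RigidTransform,
    StructureModel,
    apply_transform,
    extract_ca_trace,
    extract_metal_ions,
    output_filename,
    read_structure,
    write_structure,
)
from .superpose import (
    MLOptions,
    SuperpositionResult,
    kabsch_fit,
    mean_structure,
    ml_superpose,
    pseudo_b,
    rmsd,
    write_variances,
)
from .tree import (
    AlignmentSetConfig,
    AlignmentTreeConfig,
    SetResult,
    anchor_to_parent,
    load_tree,
    run_set,
    run_tree,
    write_set_readme,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def bundled_tree_path():
    """Path to the bundled viral-polymerase alignment-tree configuration."""
    from importlib.resources import files

    return files("poltree").joinpath("data/polymerase_tree.yaml")
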