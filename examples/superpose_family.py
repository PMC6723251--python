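"""Maximum-likelihood superposition of a synthetic Cα family.

Generates 20 traces related by random rigid transforms — tight core segments
(σ = 0.1 Å) and a divergent middle segment (σ = 1.5 Å) — runs the ML multiple
superposition, and reports how well the planted transforms are recovered and
how cleanly the per-column variances separate core from loops.
"""

import numpy as np

from poltree.fixtures import standard_family_spec, synth_family, transform_recovery_errors
from poltree.superpose import ml_superpose, pseudo_b

fam = synth_family(standard_family_spec(seed=11))
res = ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])

rot_err, trans_err = transform_recovery_errors(fam, res)
core = np.r_[res.column_variances[:20], res.column_variances[40:]]
loops = res.column_variances[20:40]

print(f"members: {len(fam.traces)}, columns: {len(res.columns_used)}, "
      f"iterations: {res.iterations} (converged: {res.converged})")
print(f"planted-transform recovery: max rotation error {rot_err.max():.3f} deg, "
      f"max translation error {trans_err.max():.3f} A")
print(f"estimated variance, core columns:  {core.mean():.4f} A^2 "
      f"(pseudo-B {pseudo_b(core).mean():.1f} A^2)")
print(f"estimated variance, loop columns:  {loops.mean():.4f} A^2 "
      f"(pseudo-B {pseudo_b(loops).mean():.1f} A^2)")
print(f"core/loop separation: {loops.mean() / core.mean():.0f}x")
print()
print("The recovery errors show the fit found each member's true orientation;")
print("the variance separation shows divergent columns were down-weighted")
print("rather than dragging the alignment (the pseudo-B column of the mean")
print("structure makes the same contrast visible in a molecular viewer).")
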