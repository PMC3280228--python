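"""Differential-expression screen on a simulated two-condition study.

Simulates 2000 probe sets (200 with a planted 2-unit log2 fold change,
3 arrays per condition), drops all-absent probes, runs the moderated t
with empirical-Bayes variance shrinkage, adjusts with BH and reports
gene-level responsiveness.
"""

from aldhkit.expression import (
    de_call,
    filter_absent,
    moderated_t,
    quantile_normalize,
    responsiveness_report,
)
from aldhkit.synthetic import ExpressionSpec, SyntheticSpec, make_expression

spec = SyntheticSpec(seed=42, expression=ExpressionSpec(
    n_genes=2000, n_planted=200, log2fc=2.0, sigma=1.0, n_per_group=3))
m, truth = make_expression(spec)

m = quantile_normalize(m)
kept, dropped = filter_absent(m)
print(f"{len(dropped)} probes absent/marginal on every array were dropped; "
      f"{len(kept.values)} tested")

res = de_call(moderated_t(kept, ("treatment", "control")), alpha=0.05)
prior = res.attrs["prior"]
print(f"empirical-Bayes prior: d0 = {prior.d0:.1f}, s0^2 = {prior.s02:.3f}")
de = res["de"]
planted = truth.loc[de.index, "planted"]
print(f"{int(de.sum())} probes DE at FDR < 0.05; "
      f"{int((de & planted).sum())} of them planted, "
      f"false-discovery proportion "
      f"{(de & ~planted).sum() / max(int(de.sum()), 1):.3f}")

report = responsiveness_report({"stress": res}, kept.probe_gene)
print("gene-level calls:", report.calls["stress"].value_counts().to_dict())
# With only three arrays per group a 2-unit shift is a modest signal:
# the screen controls the FDR at 0.05 but recovers only part of the
# planted set — the same regime the moderated t was designed for.
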