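"""Closed-form assay statistics: doubling time, ddCt, unpaired t.

The three small calculations shared by the bench assays, each printed
with its inputs.
"""

from ductnet import ddct_fold, doubling_time, unpaired_t

dt, declining = doubling_time((100, 800, 72))
print(f"100 -> 800 cells in 72 h: doubling time {dt:.1f} h "
      f"(three doublings)")

fold = ddct_fold(condition=(25.2, 20.0), control=(26.9, 20.0))
print(f"ddCt of -1.7 cycles against the housekeeping reference: "
      f"{fold:.2f}-fold expression")

t, df, p, significant = unpaired_t([1, 2, 3], [4, 5, 6])
print(f"unpaired Student t on (1,2,3) vs (4,5,6): t = {t:.3f}, "
      f"df = {df}, p = {p:.4f}, significant at 5%: {significant}")
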