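"""Corner-area effect sizes on a tiny hand-checkable sample.

Five points; the scope rectangle is 4 wide by 3 tall (area 12).  The empty
area above the CE-FDH step ceiling is 7, so the necessity effect of x on y
is 7/12: more than half the scope is a forbidden upper-left corner, i.e.
low x strongly precludes high y in this toy data.  The sufficiency effect
(empty lower-right corner) is 6/12, computed as the necessity of y on x.
"""

import numpy as np

from extnca import (
    PairedSample, compute_scope, ce_fdh_ceiling, ceiling_zone_area,
    necessity_effect, sufficiency_effect,
)

sample = PairedSample(np.array([1.0, 2, 3, 4, 5]),
                      np.array([2.0, 3, 3, 5, 4]),
                      labels=("determinant", "outcome"))

scope = compute_scope(sample)
step = ce_fdh_ceiling(sample, scope)
print(f"scope: x [{scope.x_min}, {scope.x_max}], y [{scope.y_min}, "
      f"{scope.y_max}], area {scope.area}")
print(f"ceiling steps: {step.knots}")
print(f"ceiling peers: {step.peers}")
print(f"empty upper-left area: {ceiling_zone_area(step, scope)}")

for tech in ("ce_fdh", "cr_fdh"):
    nec = necessity_effect(sample, tech)
    suf = sufficiency_effect(sample, tech)
    print(f"{tech}: necessity d = {nec.d:.4f}, sufficiency d = {suf.d:.4f}")
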