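"""Evaluate the closed-form mislabeling probability and its key geometry.

The model scores the risk that a single-attribute, median-threshold
annotator mislabels a point, given only the point's absolute deviations
(a, b) from the two attribute medians.
"""

import math

from dropal import DeviationPair, p_mislabel_directed, p_mislabel_worst

print("worst-case mislabeling probability P(a, b) = 0.5 - arctan_deg(min/max)/90\n")

for a, b in [(0.0, 5.0), (1.0, 5.0), (3.0, 5.0), (5.0, 5.0), (10.0, 2.0)]:
    est = p_mislabel_worst(DeviationPair(a, b))
    print(f"  a={a:5.1f}  b={b:5.1f}  angle={est.point_angle_deg:5.1f} deg"
          f"  P={est.probability:.3f}")

# the 0.3 drop threshold corresponds to points inclined within 18 degrees
a18 = 10 * math.tan(math.radians(18.0))
print(f"\nat 18 degrees (a={a18:.3f}, b=10): "
      f"P = {p_mislabel_worst(DeviationPair(a18, 10.0)).probability:.3f}")

# conditioning on which attribute the annotator used
pair = DeviationPair(1.0, 5.0)
for used in ("A", "B"):
    est = p_mislabel_directed(pair, used)
    print(f"annotator used attribute {used}: P = {est.probability:.3f}")
print("\nA point far off one median but near the other (small min/max ratio) is")
print("risky; equal deviations (the 45-degree line) are never mislabeled, and")
print("the worst case over the unknown attribute caps the directed variants.")
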