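"""Mask the risky attributes of a query before showing it to an annotator.

Every attribute pair is scored with the worst-case mislabeling probability
on its deviations from the medians; pairs above the 0.3 threshold nominate
their smaller-deviation member, and the top two distinct nominees are hidden.
"""

from dropal import mask_query, rank_drop_candidates

instance = [0.1, 0.2, 5.0, 4.0]
medians = [0.0, 0.0, 0.0, 0.0]

print(f"query instance:   {instance}")
print(f"population medians: {medians}\n")

print("drop candidates (attribute, probability, implicating pair):")
for cand in rank_drop_candidates(instance, medians):
    print(f"  attr {cand.attribute_index}  P={cand.probability:.3f}"
          f"  from pair {cand.source_pair}")

masked = mask_query(instance, medians)
print(f"\nvisible mask after drop-out: {masked.visible.tolist()}")
print(f"hidden attributes:           {masked.hidden_indices}")
print("\nAttributes 0 and 1 sit near their medians while 2 and 3 deviate far,")
print("so a one-attribute annotator relying on 0 or 1 would be guessing; both")
print("are hidden (capped at two), forcing the decision onto attributes 2-3.")
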