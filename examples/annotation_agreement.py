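"""Inter-annotator agreement on term annotations, per category.

Two annotators mark spans in an interaction sentence; free spans are
reduced to a rating table (merged span extents as items, category vs
not-category per annotator) and Fleiss' kappa is computed per category.
"""
from fdiforge.agreement import AnnotationSpan, kappa_by_category

sentence = "Avoid garlic and milk before milk thistle."
spans = [
    # both annotators agree garlic is a Herb and milk is a Food
    AnnotationSpan("s1", 6, 12, "Herb", "garlic", "A"),
    AnnotationSpan("s1", 6, 12, "Herb", "garlic", "B"),
    AnnotationSpan("s1", 17, 21, "Food", "milk", "A"),
    AnnotationSpan("s1", 17, 21, "Food", "milk", "B"),
    # they disagree on "milk thistle": Herb for A, Food for B
    AnnotationSpan("s1", 29, 41, "Herb", "milk thistle", "A"),
    AnnotationSpan("s1", 29, 41, "Food", "milk thistle", "B"),
]
for span in spans:
    span.validate(sentence)

for category, kappa in kappa_by_category(spans).items():
    shown = "undefined" if kappa is None else f"{kappa:.3f}"
    print(f"{category:5s} kappa = {shown}")
# Each category sees three items (the merged extents): one unanimous yes,
# one unanimous no, one split — chance-corrected agreement 1/3 for both.
# Unanimity on every item would give exactly 1.0.
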