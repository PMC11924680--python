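"""Convert measured heights to standard deviation scores on two reference scales.

A 10-year-old girl measuring 125.0 cm is scored against the pediatric LMS
reference; her parents' measured heights are scored against the adult
mean/SD reference.  The SDS values place each height relative to the
sex- (and for children, age-) matched reference population.
"""

from staturepgs import references as refs

growth = refs.synthetic_growth_reference()
adult = refs.synthetic_adult_reference()

child_sds = refs.height_to_sds(125.0, age_months=120, sex="female", ref=growth)
mother_sds = refs.adult_height_to_sds(158.0, "female", adult)
father_sds = refs.adult_height_to_sds(170.0, "male", adult)

print(f"child height 125.0 cm at age 10     -> SDS {child_sds:+.2f}")
print(f"mother height 158.0 cm              -> SDS {mother_sds:+.2f}")
print(f"father height 170.0 cm              -> SDS {father_sds:+.2f}")
print()
print("A child SDS near -2 marks clinical short stature; the parental SDS")
print("values feed the mid-parental height prediction in example 03.")
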