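"""Equivalent square field of an elongated MLC field, three ways.

The output correction factor of a small-field detector is tabulated
against the side of the equivalent square field.  For strongly elongated
fields the equivalent-area rule breaks down; the empirical elongated-field
formula (exponent 1.12) stays usable down to 0.5 cm sides.
"""

from smallfield import (
    OutOfValidityError,
    area_equivalent_square,
    equivalent_square_field,
    sterling_square,
)

a, b = 0.5, 4.0  # cm: the extreme elongated field of the 7 x 7 matrix

empirical = equivalent_square_field(a, b)
sterling = sterling_square(a, b)
print(f"field {a} x {b} cm:")
print(f"  elongated-field formula (a=1.12): {empirical.esf_cm:.4f} cm")
print(f"  Sterling (4 * area / perimeter):  {sterling.esf_cm:.4f} cm")
try:
    area_equivalent_square(a, b)
except OutOfValidityError as exc:
    print(f"  equivalent-area method: rejected ({exc})")

# The empirical side (~0.69 cm) is markedly smaller than Sterling's
# (~0.89 cm): for a 0.5 cm narrow side, the correction factor looked up at
# the Sterling side would undercorrect the detector reading.
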