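"""Physical constants (CODATA 2018), SI units.

All internal arithmetic is SI; mass-to-charge ratios cross module
boundaries in thomson (Th, Da per elementary charge).
"""

ELEMENTARY_CHARGE = 1.602176634e-19
"""Elementary charge e in coulomb (exact, SI 2019)."""

ATOMIC_MASS = 1.66053906660e-27
"""Unified atomic mass constant u in kilogram."""

#: FWHM of the magnitude of an unapodized (rectangular-window) sinc line
#: shape, in units of 1/T where T is the transient duration.  Obtained by
#: solving |sin(pi x)/(pi x)| = 1/2; used to relate fringe counts to
#: resolving power.
RECT_FWHM_FACTOR = 1.2067
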