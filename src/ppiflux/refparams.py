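"""Reference calibrated parameter sets.

These are multistart least-squares calibrations of the base model (A0)
and the secondary-pool variant (A03) against the bundled synthetic mean
curves (300 Latin-hypercube starts, log10 priors [-4, 2]).  They serve as
package-level example fits and as generating "truths" for parameter- and
model-recovery experiments; they are not fits to any experimental data.

``REFERENCE_A03`` embodies the slow-secondary-pool regime of the A03
hypothesis: its calibration constrained the exchange rates with the
dense-tubular-system pool (``theta6``, ``theta-6``) to 1e-4..1e-2 s^-1,
so the cytosolic PtdIns compartment acts as a brake.  The soluble
inositol pool Ip then stays near its initial value over the 600 s
window and PtdIns(4,5)P2 is maintained through the PI4P phosphorylation
route — the behaviour that distinguishes the secondary-pool hypothesis
from the base model, whose well-fitting solutions drain Ip completely.

All values molecules-platelet/second units as defined in
:mod:`ppiflux.models`; ``theta1`` and ``r3`` are the fixed literature
rates.
"""

from __future__ import annotations

__all__ = ["REFERENCE_A0", "REFERENCE_A03", "reference_parameters"]

REFERENCE_A0: dict[str, float] = {
    "theta1": 0.04,
    "r3": 0.0002,
    "r1": 0.0877925,
    "r-1": 0.0123038,
    "r2": 13.6054,
    "r-2": 11.172,
    "s1": 0.000100005,
    "s2": 0.0153374,
    "s-2": 0.160554,
    "r4": 0.000361312,
    "theta4": 0.000582898,
    "theta-4": 1.85521,
    "theta3": 0.402876,
    "theta-3": 0.0101072,
    "theta5": 0.00070565,
    "theta-5": 4.43072,
    "theta2": 0.0178914,
}

REFERENCE_A03: dict[str, float] = {
    "theta1": 0.04,
    "r3": 0.0002,
    "r1": 0.0170717,
    "r-1": 0.499761,
    "r2": 0.158587,
    "r-2": 0.0366289,
    "s1": 0.0001,
    "s2": 0.078219,
    "s-2": 0.00205757,
    "r4": 0.939059,
    "theta4": 0.00056809,
    "theta-4": 0.246189,
    "theta3": 0.00276913,
    "theta-3": 0.000554465,
    "theta5": 0.000294069,
    "theta-5": 0.0508545,
    "theta2": 0.101109,
    "theta6": 0.000102058,
    "theta-6": 0.00374391,
}

_REGISTRY = {"A0": REFERENCE_A0, "A03": REFERENCE_A03}


def reference_parameters(variant_id: str) -> dict[str, float]:
    """Copy of the reference calibration for ``variant_id`` (A0 or A03)."""
    if variant_id not in _REGISTRY:
        raise KeyError(f"no reference parameters for {variant_id!r}; "
                       f"available: {sorted(_REGISTRY)}")
    return dict(_REGISTRY[variant_id])
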