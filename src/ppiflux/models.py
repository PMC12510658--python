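"""Mass-action reaction networks for platelet phosphoinositide turnover.

The base model (``A0``) tracks nine molecular pools in a single platelet,
all in molecules per platelet: membrane phosphatidylinositol (``PI``),
PtdIns4P (``PI4P``), PtdIns(4,5)P2 (``PIP2``), PtdIns(3,4,5)P3 (``PIP3``),
PtdIns(3,4)P2 (``PI34P2``), a lumped pool of the unmeasured low-abundance
phosphoinositides PtdIns3P/PtdIns5P/PtdIns(3,5)P2 (``Pp``), the soluble
second messenger ``IP3``, its metabolite ``IP1``, and a lumped soluble
inositol pool (``Ip``) that is recycled back to membrane PtdIns.

Receptor-proximal signalling downstream of the collagen receptor GPVI
(Syk/LAT/Btk/PLCgamma2 phosphorylation) is summarised by a dimensionless
stimulus function ``s(t)`` that multiplies the PLC- and PI3K-mediated
fluxes out of PtdIns(4,5)P2.

Ten variants (``A01``..``A10``) each add a single candidate regulatory
mechanism to ``A0``: stimulus- or metabolite-promotion of an existing flux,
a sequestered pool (cytosolic PtdIns, protein-bound PIP3 or PIP2), or an
extra conversion route.  Every model is a closed system: each reaction
moves molecules from one pool to another, so the total count is conserved.

Rate constants are first order (s^-1) except where a reaction carries a
modifier species, in which case the constant is per (molecules/platelet)
per second.  Reverse rates are named with a ``-`` infix (``r-1`` is the
reverse of ``r1``, ``theta-3`` the reverse of ``theta3``).  ``theta1``
(IP3 -> IP1) and ``r3`` (IP1 -> Ip) are fixed from literature kinetics and
are never fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusParams",
    "DEFAULT_STIMULUS",
    "stimulus",
    "Reaction",
    "ModelSpec",
    "build_model",
    "all_variants",
    "rhs_eval",
    "FIXED_PARAMETERS",
    "VARIANT_IDS",
]

#: theta1 (IP3 -> IP1) and r3 (IP1 -> Ip), s^-1; literature-derived, never fitted.
FIXED_PARAMETERS: dict[str, float] = {"theta1": 0.04, "r3": 0.0002}

VARIANT_IDS = (
    "A0", "A01", "A02", "A03", "A04", "A05",
    "A06", "A07", "A08", "A09", "A10",
)

_A0_STATES = ("PI", "PI4P", "PIP2", "PIP3", "PI34P2", "Pp", "IP3", "IP1", "Ip")


@dataclass(frozen=True)
class StimulusParams:
    """Parameters of the GPVI stimulus s(t) = a1*t*exp(-a2*t^2) + a3*tanh(a4*t).

    ``a1`` (s^-1) and ``a2`` (s^-2) shape an early transient peak, ``a3``
    (dimensionless) is the late plateau and ``a4`` (s^-1) its rise rate.
    The defaults are the calibration stimulus.
    """

    a1: float = 0.001
    a2: float = 0.0002
    a3: float = 1.0
    a4: float = 0.02

    def __post_init__(self) -> None:
        if self.a2 < 0 or self.a4 < 0:
            raise ValueError("stimulus decay a2 and rise rate a4 must be >= 0")


DEFAULT_STIMULUS = StimulusParams()


def stimulus(t, params: StimulusParams = DEFAULT_STIMULUS):
    """Evaluate the dimensionless stimulus level at time ``t`` (seconds).

    Accepts a scalar or array; negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("stimulus is defined for t >= 0 only")
    out = params.a1 * t_arr * np.exp(-params.a2 * t_arr * t_arr) + params.a3 * np.tanh(
        params.a4 * t_arr
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class Reaction:
    """One mass-action conversion ``source -> dest``.

    Flux = ``k * [source]``, optionally multiplied by ``[modifier]`` (a
    promoting species, making the rate constant second order) and/or by the
    stimulus level ``s(t)``.
    """

    param: str
    source: str
    dest: str
    modifier: str | None = None
    stimulated: bool = False


def _a0_reactions() -> list[Reaction]:
    return [
        Reaction("r1", "PI", "PI4P"),
        Reaction("r-1", "PI4P", "PI"),
        Reaction("r2", "PI4P", "PIP2"),
        Reaction("r-2", "PIP2", "PI4P"),
        Reaction("s1", "PIP2", "IP3", stimulated=True),
        Reaction("s2", "PIP2", "PIP3", stimulated=True),
        Reaction("s-2", "PIP3", "PIP2"),
        Reaction("r4", "PIP3", "PI34P2"),
        Reaction("theta4", "Pp", "PI34P2"),
        Reaction("theta-4", "PI34P2", "Pp"),
        Reaction("theta3", "PI", "Pp"),
        Reaction("theta-3", "Pp", "PI"),
        Reaction("theta5", "Pp", "PIP2"),
        Reaction("theta-5", "PIP2", "Pp"),
        Reaction("theta1", "IP3", "IP1"),
        Reaction("r3", "IP1", "Ip"),
        Reaction("theta2", "Ip", "PI"),
    ]


def _replace(reactions: list[Reaction], param: str, **changes) -> list[Reaction]:
    out = []
    for r in reactions:
        if r.param == param:
            d = {"param": r.param, "source": r.source, "dest": r.dest,
                 "modifier": r.modifier, "stimulated": r.stimulated}
            d.update(changes)
            r = Reaction(**d)
        out.append(r)
    return out


class ModelSpec:
    """A pathway variant: ordered states, reactions, and a compiled RHS.

    The right-hand side is assembled from the reaction list through a
    stoichiometry matrix, so the componentwise sum of the derivative is
    structurally zero and every loss term carries its own species'
    abundance (non-negative states can never be driven negative by an
    instantaneous rate).
    """

    def __init__(self, variant_id: str, state_names: Sequence[str],
                 reactions: Sequence[Reaction], description: str = ""):
        self.variant_id = variant_id
        self.state_names = tuple(state_names)
        self.reactions = tuple(reactions)
        self.description = description
        self.n_states = len(self.state_names)
        idx = {s: i for i, s in enumerate(self.state_names)}
        for r in self.reactions:
            for s in (r.source, r.dest) + ((r.modifier,) if r.modifier else ()):
                if s not in idx:
                    raise ValueError(f"{variant_id}: unknown state {s!r} in reaction {r}")

        self.parameter_names = tuple(dict.fromkeys(r.param for r in self.reactions))
        self.fixed_parameters = dict(FIXED_PARAMETERS)
        self.free_parameter_names = tuple(
            p for p in self.parameter_names if p not in self.fixed_parameters
        )

        n_rxn = len(self.reactions)
        self._src = np.array([idx[r.source] for r in self.reactions], dtype=np.intp)
        self._mod = np.array(
            [idx[r.modifier] if r.modifier else 0 for r in self.reactions], dtype=np.intp
        )
        self._has_mod = np.array([r.modifier is not None for r in self.reactions])
        self._stim = np.array([r.stimulated for r in self.reactions])
        self._any_mod = bool(self._has_mod.any())
        S = np.zeros((self.n_states, n_rxn))
        for j, r in enumerate(self.reactions):
            S[idx[r.source], j] -= 1.0
            S[idx[r.dest], j] += 1.0
        self._stoich = S

    # -- parameters ---------------------------------------------------------

    @property
    def n_free_parameters(self) -> int:
        """K, the number of parameters inferred from data."""
        return len(self.free_parameter_names)

    def full_parameters(self, params: Mapping[str, float]) -> dict[str, float]:
        """Merge user parameters with the fixed theta1/r3 values.

        Explicit entries for fixed parameters are honoured if given.
        """
        full = dict(self.fixed_parameters)
        full.update(params)
        return full

    def rate_vector(self, params: Mapping[str, float]) -> np.ndarray:
        """Per-reaction rate constants in reaction order; all must be >= 0."""
        full = self.full_parameters(params)
        try:
            k = np.array([full[r.param] for r in self.reactions], dtype=float)
        except KeyError as err:
            raise KeyError(
                f"{self.variant_id}: missing rate constant {err.args[0]!r}"
            ) from None
        if np.any(k < 0) or not np.all(np.isfinite(k)):
            raise ValueError(f"{self.variant_id}: rate constants must be finite and >= 0")
        return k

    def parameter_units(self) -> dict[str, str]:
        """Units per rate constant; second order where a modifier promotes it."""
        units = {p: "s^-1" for p in self.parameter_names}
        for r in self.reactions:
            if r.modifier is not None:
                units[r.param] = "(molecules platelet^-1)^-1 s^-1"
        return units

    # -- right-hand side ----------------------------------------------------

    def rhs_factory(
        self, kvec: np.ndarray, stim: StimulusParams = DEFAULT_STIMULUS
    ) -> Callable[[float, np.ndarray], np.ndarray]:
        """Compile ``f(t, y) -> dy/dt`` for a fixed rate vector and stimulus."""
        src, mod, has_mod = self._src, self._mod, self._has_mod
        stim_mask, S = self._stim, self._stoich
        any_mod = self._any_mod
        a1, a2, a3, a4 = stim.a1, stim.a2, stim.a3, stim.a4

        def f(t: float, y: np.ndarray) -> np.ndarray:
            rates = kvec * y[src]
            if any_mod:
                rates = np.where(has_mod, rates * y[mod], rates)
            s = a1 * t * math.exp(-a2 * t * t) + a3 * math.tanh(a4 * t)
            rates = np.where(stim_mask, rates * s, rates)
            return S @ rates

        return f

    def rhs(self, t: float, state: np.ndarray, params: Mapping[str, float],
            stim: StimulusParams = DEFAULT_STIMULUS) -> np.ndarray:
        """Instantaneous rates of change, molecules platelet^-1 s^-1."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_states,):
            raise ValueError(
                f"{self.variant_id}: state length {state.shape} != {self.n_states}"
            )
        return self.rhs_factory(self.rate_vector(params), stim)(float(t), state)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ModelSpec({self.variant_id!r}, {self.n_states} states, "
                f"K={self.n_free_parameters})")


def _build_variant(variant_id: str) -> ModelSpec:
    states = list(_A0_STATES)
    rxn = _a0_reactions()
    desc = "baseline mass-action pathway"
    if variant_id == "A0":
        pass
    elif variant_id == "A01":
        # SHIP1/2 recruitment: stimulus promotes PIP3 -> PI34P2.
        rxn = _replace(rxn, "r4", stimulated=True)
        desc = "stimulus promotes r4 (PIP3 -> PI34P2)"
    elif variant_id == "A02":
        # PKC/Rac1 via Ca2+ (IP3 surrogate) promotes PI4P -> PIP2.
        rxn = _replace(rxn, "r2", modifier="IP3")
        desc = "IP3 promotes r2 (PI4P -> PIP2)"
    elif variant_id == "A03":
        # Secondary PtdIns pool in the dense tubular system; recycled inositol
        # passes through PIc before returning to membrane PI.
        states.append("PIc")
        rxn = _replace(rxn, "theta2", source="PIc")
        rxn += [Reaction("theta6", "Ip", "PIc"), Reaction("theta-6", "PIc", "Ip")]
        desc = "secondary PtdIns pool PIc; theta2 reassigned to PIc -> PI"
    elif variant_id == "A04":
        # PH-domain (Btk) binding sequesters PIP3; binding is stimulus-driven.
        states.append("PIP3b")
        rxn += [
            Reaction("s4", "PIP3", "PIP3b", stimulated=True),
            Reaction("s-4", "PIP3b", "PIP3"),
        ]
        desc = "stimulus-driven PIP3 sequestration into PIP3b"
    elif variant_id == "A05":
        # MARCKS sequesters PIP2; Ca2+ (IP3 surrogate) promotes release.
        states.append("PIP2b")
        rxn += [
            Reaction("s5", "PIP2", "PIP2b"),
            Reaction("s-5", "PIP2b", "PIP2", modifier="IP3"),
        ]
        desc = "PIP2 sequestration into PIP2b; IP3 promotes release"
    elif variant_id == "A06":
        # Membrane contact sites: Ca2+ (IP3 surrogate) promotes PI -> PI4P.
        rxn = _replace(rxn, "r1", modifier="IP3")
        desc = "IP3 promotes r1 (PI -> PI4P)"
    elif variant_id == "A07":
        # Osh/Sac1: PI4P promotes its own dephosphorylation to PI.
        rxn = _replace(rxn, "r-1", modifier="PI4P")
        desc = "PI4P promotes r-1 (PI4P -> PI)"
    elif variant_id == "A08":
        # PtdIns 4-kinase: PIP2 increases Pp -> PI34P2.
        rxn = _replace(rxn, "theta4", modifier="PIP2")
        desc = "PIP2 promotes theta4 (Pp -> PI34P2)"
    elif variant_id == "A09":
        # PIK3C2A route: direct PI4P -> PI34P2 synthesis.
        rxn.append(Reaction("r6", "PI4P", "PI34P2"))
        desc = "extra flux r6 (PI4P -> PI34P2)"
    elif variant_id == "A10":
        # cPLA2/LPI shunt: IP3-promoted diversion of membrane PI to the
        # soluble inositol pool.
        rxn.append(Reaction("theta-2", "PI", "Ip", modifier="IP3"))
        desc = "extra IP3-promoted flux theta-2 (PI -> Ip)"
    else:
        raise ValueError(f"unknown model variant {variant_id!r}; "
                         f"expected one of {VARIANT_IDS}")
    return ModelSpec(variant_id, states, rxn, desc)


@lru_cache(maxsize=None)
def build_model(variant_id: str) -> ModelSpec:
    """Return the :class:`ModelSpec` for one of the eleven variants."""
    return _build_variant(variant_id)


def all_variants() -> tuple[ModelSpec, ...]:
    """The full eleven-model catalogue, A0 first."""
    return tuple(build_model(v) for v in VARIANT_IDS)


def rhs_eval(spec: ModelSpec, t: float, state, params: Mapping[str, float],
             stim: StimulusParams = DEFAULT_STIMULUS) -> np.ndarray:
    """Functional form of :meth:`ModelSpec.rhs` (same contract)."""
    return spec.rhs(t, np.asarray(state, dtype=float), params, stim)
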