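"""Discrete control architectures and metabolite dose-response functions.

A control architecture wires pathway intermediates ("ligands", metabolites
that bind a transcription factor or riboregulator) to the promoters driving
heterologous enzyme expression. Each wire is signed: repression (-1) or
activation (+1). Whether a wire closes a negative or positive feedback loop
depends on where the controlled enzyme sits relative to the ligand: repressing
a ligand-producing (upstream) enzyme or activating a ligand-consuming
(downstream) enzyme is negative feedback; the opposite pairings are positive
feedback and are excluded from the feasible design space because they are
prone to multistability.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "ConfigurationError",
    "DomainError",
    "Promoter",
    "RegulatorySpec",
    "ArchitectureSpec",
    "DoseResponseParams",
    "hill_response",
    "enzyme_expression_rates",
    "loop_sign",
    "enumerate_architectures",
]


class ConfigurationError(ValueError):
    """Inconsistent model / architecture / parameter wiring."""


class DomainError(ValueError):
    """Numerical input outside its physical domain (e.g. negative concentration)."""


Position = Literal["upstream", "downstream"]
Mode = Literal["activation", "repression"]

#: matrix sign that realises *negative* feedback at each position
NEGATIVE_SIGN: dict[Position, int] = {"upstream": -1, "downstream": +1}


@dataclass(frozen=True)
class Promoter:
    """An expression unit: one promoter driving one or more enzymes (operon)."""

    name: str
    enzymes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ConfigurationError(f"promoter {self.name!r} expresses no enzyme")


@dataclass(frozen=True)
class RegulatorySpec:
    """Which metabolites can act as ligands, and where each promoter's enzymes sit
    (upstream = producing the ligand, downstream = consuming it)."""

    ligands: tuple[str, ...]
    promoters: tuple[Promoter, ...]
    position_map: Mapping[tuple[str, str], Position]

    def __post_init__(self) -> None:
        if not self.ligands or not self.promoters:
            raise ConfigurationError("ligands and promoters must be non-empty")
        for lig, prom in itertools.product(self.ligands, self.promoters):
            if (lig, prom.name) not in self.position_map:
                raise ConfigurationError(
                    f"position_map missing entry for ({lig!r}, {prom.name!r})"
                )

    @property
    def promoter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.promoters)

    @property
    def enzymes(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.promoters:
            out.extend(p.enzymes)
        return tuple(out)


@dataclass(frozen=True)
class ArchitectureSpec:
    """A single point in the discrete design space p_d.

    Either a signed ligand x promoter control matrix (entries in {-1, 0, +1};
    at most one ligand per promoter) or, for models whose architectures switch
    whole model functions, a categorical label.
    """

    encoding_kind: Literal["matrix", "categorical"]
    control_matrix: tuple[tuple[int, ...], ...] | None = None
    categorical_label: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if (self.control_matrix is None) == (self.categorical_label is None):
            raise ConfigurationError(
                "exactly one of control_matrix / categorical_label must be set"
            )
        if self.encoding_kind == "matrix":
            m = np.asarray(self.control_matrix, dtype=int)
            if m.ndim != 2:
                raise ConfigurationError("control_matrix must be 2-D (ligands x promoters)")
            if not np.isin(m, (-1, 0, 1)).all():
                raise ConfigurationError("control_matrix entries must be in {-1, 0, +1}")
            if (np.count_nonzero(m, axis=0) > 1).any():
                raise ConfigurationError("a promoter may be controlled by at most one ligand")
        elif self.categorical_label is None:
            raise ConfigurationError("categorical encoding requires categorical_label")

    @property
    def matrix(self) -> np.ndarray:
        if self.control_matrix is None:
            raise ConfigurationError("architecture has no matrix encoding")
        return np.asarray(self.control_matrix, dtype=int)

    def is_open_loop(self) -> bool:
        if self.encoding_kind == "categorical":
            return self.categorical_label == "open_loop"
        return not self.matrix.any()

    def controller_of(self, promoter_index: int) -> tuple[int, int] | None:
        """(ligand index, sign) controlling the given promoter, or None."""
        col = self.matrix[:, promoter_index]
        nz = np.flatnonzero(col)
        if nz.size == 0:
            return None
        return int(nz[0]), int(col[nz[0]])

    def to_json(self) -> str:
        payload = {
            "encoding": self.encoding_kind,
            "matrix": [list(r) for r in self.control_matrix] if self.control_matrix else None,
            "label": self.categorical_label,
            "name": self.name,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        return cls(
            encoding_kind=d["encoding"],
            control_matrix=tuple(tuple(r) for r in d["matrix"]) if d.get("matrix") else None,
            categorical_label=d.get("label"),
            name=d.get("name", ""),
        )


@dataclass(frozen=True)
class DoseResponseParams:
    """Hill dose-response of one controlled promoter: maximal expression rate k
    (concentration/time), regulatory threshold theta (concentration), and Hill
    coefficient n (dimensionless, default 2)."""

    k: float
    theta: float
    n: float = 2.0

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.theta > 0):
            raise DomainError("dose-response k and theta must be positive")
        if self.n < 1:
            raise DomainError("Hill coefficient must be >= 1")


@dataclass(frozen=True)
class ConstitutiveParams:
    """Constant expression rate of an uncontrolled promoter."""

    k0: float

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise DomainError("constitutive rate must be non-negative")


def hill_response(s: float, p: DoseResponseParams, mode: Mode) -> float:
    """Expression rate driven by ligand concentration ``s``.

    Activation: k * s^n / (theta^n + s^n); repression: k * theta^n / (theta^n + s^n).
    Result lies in [0, k].
    """
    if s < 0:
        raise DomainError(f"ligand concentration must be non-negative, got {s}")
    sn = (s / p.theta) ** p.n
    if mode == "activation":
        return p.k * sn / (1.0 + sn)
    if mode == "repression":
        return p.k / (1.0 + sn)
    raise ConfigurationError(f"unknown mode {mode!r}")


def enzyme_expression_rates(
    ligand_conc: Mapping[str, float],
    p_c: Mapping[str, DoseResponseParams | ConstitutiveParams],
    arch: ArchitectureSpec,
    spec: RegulatorySpec,
) -> dict[str, float]:
    """Expression-rate vector u(s, p_c, p_d): one rate per enzyme.

    ``p_c`` maps each promoter name to its dose-response parameters (if the
    promoter is controlled in ``arch``) or its constitutive rate. An operon
    promoter broadcasts its single rate to every member enzyme.
    """
    if arch.encoding_kind != "matrix":
        raise ConfigurationError("expression rates from matrix-encoded architectures only")
    if set(p_c) != set(spec.promoter_names):
        raise ConfigurationError(
            f"p_c keys {sorted(p_c)} do not match promoters {sorted(spec.promoter_names)}"
        )
    rates: dict[str, float] = {}
    for j, prom in enumerate(spec.promoters):
        ctrl = arch.controller_of(j)
        params = p_c[prom.name]
        if ctrl is None:
            if not isinstance(params, ConstitutiveParams):
                raise ConfigurationError(
                    f"uncontrolled promoter {prom.name!r} needs ConstitutiveParams"
                )
            rate = params.k0
        else:
            if not isinstance(params, DoseResponseParams):
                raise ConfigurationError(
                    f"controlled promoter {prom.name!r} needs DoseResponseParams"
                )
            lig_idx, sign = ctrl
            mode: Mode = "repression" if sign < 0 else "activation"
            s = ligand_conc[spec.ligands[lig_idx]]
            rate = hill_response(s, params, mode)
        for enz in prom.enzymes:
            rates[enz] = rate
    return rates


def loop_sign(arch: ArchitectureSpec, spec: RegulatorySpec) -> dict[tuple[str, str], str]:
    """Feedback sign of every nonzero control edge.

    Repression of an upstream (ligand-producing) enzyme or activation of a
    downstream (ligand-consuming) enzyme closes a negative loop; the opposite
    pairings are positive.
    """
    if arch.encoding_kind != "matrix":
        raise ConfigurationError("loop_sign requires a matrix-encoded architecture")
    signs: dict[tuple[str, str], str] = {}
    m = arch.matrix
    for i, lig in enumerate(spec.ligands):
        for j, prom in enumerate(spec.promoters):
            entry = m[i, j]
            if entry == 0:
                continue
            pos = spec.position_map[(lig, prom.name)]
            negative = entry == NEGATIVE_SIGN[pos]
            signs[(lig, prom.name)] = "negative" if negative else "positive"
    return signs


def _default_name(m: np.ndarray, spec: RegulatorySpec) -> str:
    if not m.any():
        return "open_loop"
    parts = []
    for j, prom in enumerate(spec.promoters):
        col = m[:, j]
        for i in np.flatnonzero(col):
            verb = "rep" if col[i] < 0 else "act"
            parts.append(f"{verb}({spec.ligands[i]}->{prom.name})")
    return "+".join(parts)


def enumerate_architectures(
    spec: RegulatorySpec,
    names: Mapping[tuple[tuple[int, ...], ...], str] | None = None,
) -> list[ArchitectureSpec]:
    """All feasible matrix architectures: each promoter is uncontrolled or
    negatively controlled by exactly one ligand (no positive-feedback edges).

    The list always contains the open-loop (all-zero) architecture and is
    ordered lexicographically over the flattened matrix entries, so the count
    is prod_p (1 + #ligands allowed for promoter p)."""
    L, P = len(spec.ligands), len(spec.promoters)
    per_promoter: list[list[tuple[int, int]]] = []  # (ligand index or -1, sign)
    for prom in spec.promoters:
        choices: list[tuple[int, int]] = [(-1, 0)]
        for i, lig in enumerate(spec.ligands):
            pos = spec.position_map[(lig, prom.name)]
            choices.append((i, NEGATIVE_SIGN[pos]))
        per_promoter.append(choices)

    archs: list[ArchitectureSpec] = []
    for combo in itertools.product(*per_promoter):
        m = np.zeros((L, P), dtype=int)
        for j, (i, sign) in enumerate(combo):
            if i >= 0:
                m[i, j] = sign
        key = tuple(tuple(int(v) for v in row) for row in m)
        name = (names or {}).get(key) or _default_name(m, spec)
        archs.append(ArchitectureSpec("matrix", control_matrix=key, name=name))
    archs.sort(key=lambda a: tuple(np.asarray(a.control_matrix).ravel()))
    return archs
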