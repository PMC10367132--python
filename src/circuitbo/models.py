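"""Multiscale pathway ODE models under genetic feedback control.

Each model couples fast metabolic mass balances with slow enzyme expression:

    ds/dt = f(s, e) + influx/export,      de/dt = u(s, p_c, p_d) - lambda * e

where ``s`` are metabolite concentrations (mM), ``e`` heterologous protein
concentrations (uM), ``u`` the architecture-dependent expression rates
(uM/h) and ``lambda`` the dilution rate by cell growth (1/h). Time is in
hours. The scale separation between metabolism (sub-second turnover) and
expression (hours) makes the systems stiff, so trajectories are computed
with an implicit BDF-class integrator (LSODA, which switches to backward
differentiation on stiff segments; plain BDF is available via ``method``).

Four built-in models ship as fixtures: a toy branch-point pathway, the
glucaric acid pathway (explicit Ino1/MIOX with allosteric MIOX activation
and myo-inositol export), a fatty acid pathway with metabolic/genetic
repressor loops, and the 23-state p-aminostyrene pathway with mRNA dynamics,
protein folding, an efflux pump and a multiplicative toxicity factor.

Exact rate laws and nominal parameter values are the package's own model
cards (irreversible Michaelis-Menten steps, first-order export/leak terms);
``model_card`` records the provenance of every number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

from .architectures import (
    ArchitectureSpec,
    ConfigurationError,
    ConstitutiveParams,
    DomainError,
    DoseResponseParams,
    Promoter,
    RegulatorySpec,
    enumerate_architectures,
)

__all__ = [
    "KineticParams",
    "ToxicityParams",
    "SimulationResult",
    "PathwayModel",
    "build_model",
    "miox_rate",
    "toxicity_factor",
    "simulate",
    "steady_state_init",
    "MODEL_IDS",
]

MODEL_IDS = ("toy", "glucaric_acid", "fatty_acid", "p_aminostyrene")

#: loss assigned to failed / non-finite integrations (kept finite so the
#: optimization loop stays total)
PENALTY_LOSS = 1.0e9

_SS_RTOL = 1e-8          # steady-state relative residual threshold
_SS_HORIZON = 1.0e4      # max horizon (h) for steady-state search
_DEFAULT_RTOL = 1e-6
_DEFAULT_ATOL = 1e-9


class KineticParams(dict):
    """Positive kinetic constants with named lookup by symbol."""

    def __init__(self, **values: float):
        for name, v in values.items():
            if not (v > 0 and np.isfinite(v)):
                raise ConfigurationError(f"kinetic parameter {name}={v} must be positive")
        super().__init__(**values)

    def replace(self, **overrides: float) -> "KineticParams":
        unknown = set(overrides) - set(self)
        if unknown:
            raise ConfigurationError(f"unknown kinetic parameters: {sorted(unknown)}")
        merged = dict(self)
        merged.update(overrides)
        return KineticParams(**merged)


@dataclass(frozen=True)
class ToxicityParams:
    """Chemical-specific toxicity factors (dimensionless, non-negative).

    t_l scales the burden of LAAO-driven metabolite depletion, t_a the impact
    of the toxic intermediate p-ACA, t_p the burden of efflux-pump expression.
    """

    t_l: float = 0.0
    t_a: float = 0.0
    t_p: float = 0.0

    def __post_init__(self) -> None:
        if min(self.t_l, self.t_a, self.t_p) < 0:
            raise ConfigurationError("toxicity factors must be non-negative")


@dataclass
class SimulationResult:
    """Time grid (h), state trajectories (rows = time points), solver status."""

    t: np.ndarray
    y: np.ndarray
    success: bool
    message: str = ""
    state_names: tuple[str, ...] = ()
    steady_state: bool = False

    def state(self, name: str) -> np.ndarray:
        return self.y[:, self.state_names.index(name)]


def miox_rate(s_mi: float, e_miox: float, params: Mapping[str, float]) -> float:
    """Rate of the MIOX step: Michaelis-Menten in myo-inositol with an
    allosteric activation factor in the same substrate,

        v = Vm * e * s/(km + s) * (1 + a * s/(ka + s)).

    Monotone increasing in ``s_mi``, proportional to ``e_miox`` and bounded by
    Vm * e * (1 + a).
    """
    if s_mi < 0 or e_miox < 0:
        raise DomainError("miox_rate requires non-negative concentrations")
    vm, km = params["Vm_MIOX"], params["km_MIOX"]
    ka, a = params["ka_MIOX"], params["a_MIOX"]
    return vm * e_miox * s_mi / (km + s_mi) * (1.0 + a * s_mi / (ka + s_mi))


def toxicity_factor(state: Mapping[str, float], tox: ToxicityParams) -> float:
    """Multiplicative burden factor tau in (0, 1], applied to synthesis,
    degradation and folding rates of the p-AS model:

        tau = 1 / (1 + t_l * v_LAAO + t_a * [p-ACA] + t_p * [pump])

    tau = 1 with all factors zero; decreasing in each burden source; clamped
    at a small positive floor.
    """
    burden = (
        tox.t_l * max(state.get("v_LAAO", 0.0), 0.0)
        + tox.t_a * max(state.get("pACA", 0.0), 0.0)
        + tox.t_p * max(state.get("Pump", 0.0), 0.0)
    )
    return max(1.0 / (1.0 + burden), 1e-6)


def _hill_terms(s: float, theta: float, n: float) -> float:
    """x = (s/theta)^n with negative transients clipped to zero."""
    return (max(s, 0.0) / theta) ** n


@dataclass
class PathwayModel:
    """A fully parameterized pathway model exposing the joint right-hand side
    h(x) of the metabolite/enzyme split and its design-space metadata."""

    model_id: str
    metabolites: tuple[str, ...]
    proteins: tuple[str, ...]            # heterologous protein states (folded enzymes)
    extra_states: tuple[str, ...]        # mRNA / unfolded-protein states (p-AS)
    kinetics: KineticParams
    dilution: float                      # lambda, 1/h
    v_in: float                          # constant pathway influx, mM/h
    regulatory_spec: RegulatorySpec | None
    pc_names: tuple[str, ...]
    pc_bounds: tuple[tuple[float, float], ...]
    pc_defaults: tuple[float, ...]
    hill_n: float = 2.0
    toxicity: ToxicityParams = field(default_factory=ToxicityParams)
    t_span: tuple[float, float] = (0.0, 24.0)
    n_grid: int = 241
    #: (alpha1, alpha2) calibrated for the cost-benefit loss via
    #: objectives.calibrate_weights(seed=0); alpha2 balances the median
    #: enzyme-cost term against the median reciprocal-flux term
    default_cost_weights: tuple[float, float] = (1.0, 1.0)
    arch_names: dict = field(default_factory=dict)
    categorical_archs: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    _arch_cache: list | None = field(default=None, repr=False)
    _rhs: Callable | None = field(default=None, repr=False)
    _product_flux: Callable | None = field(default=None, repr=False)

    # ---- structure -------------------------------------------------------
    @property
    def state_names(self) -> tuple[str, ...]:
        return self.metabolites + self.extra_states + self.proteins

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_continuous(self) -> int:
        return len(self.pc_names)

    @property
    def heterologous_indices(self) -> np.ndarray:
        n_m = len(self.metabolites)
        return np.arange(n_m, self.n_states)

    def architectures(self) -> list[ArchitectureSpec]:
        """Feasible discrete design space p_d (deterministic order)."""
        if self._arch_cache is None:
            if self.categorical_archs:
                self._arch_cache = [
                    ArchitectureSpec("categorical", categorical_label=lab, name=lab)
                    for lab in self.categorical_archs
                ]
            else:
                self._arch_cache = enumerate_architectures(
                    self.regulatory_spec, names=self.arch_names
                )
        return self._arch_cache

    def architecture_by_name(self, name: str) -> ArchitectureSpec:
        for a in self.architectures():
            if a.name == name:
                return a
        raise ConfigurationError(f"unknown architecture {name!r} for {self.model_id}")

    # ---- continuous decision vector -------------------------------------
    def promoter_params(
        self, p_c: Sequence[float], arch: ArchitectureSpec
    ) -> dict[str, DoseResponseParams | ConstitutiveParams]:
        """Map the flat decision vector p_c onto per-promoter parameters for
        the given architecture (uncontrolled promoters fall back to the
        constitutive rate encoded in the same vector)."""
        raise NotImplementedError

    def validate_pc(self, p_c: Sequence[float]) -> np.ndarray:
        p = np.asarray(p_c, dtype=float)
        if p.shape != (self.n_continuous,):
            raise ConfigurationError(
                f"{self.model_id} expects {self.n_continuous} continuous parameters, "
                f"got shape {p.shape}"
            )
        return p

    # ---- dynamics --------------------------------------------------------
    def rhs(self, t: float, x: np.ndarray, arch: ArchitectureSpec, p_c: np.ndarray):
        return self._rhs(t, x, arch, p_c)

    def product_flux(self, y: np.ndarray) -> np.ndarray:
        """Instantaneous production flux along a trajectory (rows = times)."""
        return self._product_flux(np.atleast_2d(y))

    def enzyme_cost(self, y: np.ndarray) -> np.ndarray:
        """Total heterologous protein concentration along a trajectory."""
        return np.atleast_2d(y)[:, self.heterologous_indices].sum(axis=1)

    def model_card(self) -> dict:
        return {
            "model_id": self.model_id,
            "states": list(self.state_names),
            "metabolites": list(self.metabolites),
            "proteins": list(self.proteins),
            "kinetics": dict(self.kinetics),
            "dilution": self.dilution,
            "v_in": self.v_in,
            "hill_n": self.hill_n,
            "toxicity": vars(self.toxicity),
            "pc_names": list(self.pc_names),
            "pc_bounds": [list(b) for b in self.pc_bounds],
            "provenance": dict(self.provenance),
        }


# ---------------------------------------------------------------------------
# control-term helpers shared by the matrix-encoded models
# ---------------------------------------------------------------------------

def _matrix_promoter_params(model: PathwayModel, p_c, arch, layout):
    """layout: promoter name -> (k_index, theta_index)."""
    p = model.validate_pc(p_c)
    spec = model.regulatory_spec
    out: dict[str, DoseResponseParams | ConstitutiveParams] = {}
    for j, prom in enumerate(spec.promoters):
        k_idx, th_idx = layout[prom.name]
        if arch.controller_of(j) is None:
            out[prom.name] = ConstitutiveParams(k0=p[k_idx])
        else:
            out[prom.name] = DoseResponseParams(
                k=p[k_idx], theta=p[th_idx], n=model.hill_n
            )
    return out


def _compiled_control(model: PathwayModel, arch: ArchitectureSpec, layout):
    """Per-promoter control recipe: (mode, ligand state index, k idx, theta idx)
    with mode in {0: constitutive, -1: repression, +1: activation}."""
    spec = model.regulatory_spec
    recipe = []
    for j, prom in enumerate(spec.promoters):
        k_idx, th_idx = layout[prom.name]
        ctrl = arch.controller_of(j)
        if ctrl is None:
            recipe.append((0, -1, k_idx, th_idx))
        else:
            lig_idx, sign = ctrl
            s_idx = model.state_names.index(spec.ligands[lig_idx])
            recipe.append((sign, s_idx, k_idx, th_idx))
    return recipe


def _promoter_rates(x, p_c, recipe, n):
    rates = np.empty(len(recipe))
    for j, (mode, s_idx, k_idx, th_idx) in enumerate(recipe):
        if mode == 0:
            rates[j] = p_c[k_idx]
        else:
            h = _hill_terms(x[s_idx], p_c[th_idx], n)
            rates[j] = p_c[k_idx] * (h / (1.0 + h) if mode > 0 else 1.0 / (1.0 + h))
    return rates


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

_KTH_BOUNDS = ((1e-3, 15.0), (1e-2, 1.0))  # k (uM/h), theta (mM)


def _build_toy(kin: KineticParams, lam, v_in, hill_n, tox) -> PathwayModel:
    spec = RegulatorySpec(
        ligands=("X1",),
        promoters=(Promoter("P1", ("E1",)), Promoter("P2", ("E2",))),
        position_map={("X1", "P1"): "upstream", ("X1", "P2"): "downstream"},
    )
    names = {
        ((0, 0),): "open_loop",
        ((-1, 0),): "upstream_repression",
        ((0, 1),): "downstream_activation",
        ((-1, 1),): "dual_control",
    }
    model = PathwayModel(
        model_id="toy",
        metabolites=("X0", "X1"),
        proteins=("E1", "E2"),
        extra_states=(),
        kinetics=kin,
        dilution=lam,
        v_in=v_in,
        regulatory_spec=spec,
        pc_names=("k1", "theta1", "k2", "theta2"),
        pc_bounds=_KTH_BOUNDS * 2,
        pc_defaults=(5.0, 1.0, 5.0, 1.0),
        hill_n=hill_n,
        t_span=(0.0, 12.0),
        n_grid=121,
        default_cost_weights=(1.0, 0.0566),
        arch_names=names,
        provenance={"structure": "branch point feeding two heterologous steps", "parameters": "synthetic-nominal"},
    )
    layout = {"P1": (0, 1), "P2": (2, 3)}
    model.promoter_params = lambda p_c, arch: _matrix_promoter_params(model, p_c, arch, layout)

    kcat1, Km1 = kin["kcat1"], kin["Km1"]
    kcat2, Km2 = kin["kcat2"], kin["Km2"]
    k_nat = kin["k_nat"]

    recipe_cache: dict = {}

    def rhs(t, x, arch, p_c):
        rec = recipe_cache.get(id(arch))
        if rec is None:
            rec = recipe_cache[id(arch)] = _compiled_control(model, arch, layout)
        s0, s1, e1, e2 = x
        v1 = kcat1 * e1 * max(s0, 0.0) / (Km1 + max(s0, 0.0))
        v2 = kcat2 * e2 * max(s1, 0.0) / (Km2 + max(s1, 0.0))
        u = _promoter_rates(x, p_c, rec, model.hill_n)
        lam_ = model.dilution
        return np.array([
            model.v_in - k_nat * s0 - v1,
            v1 - v2,
            u[0] - lam_ * e1,
            u[1] - lam_ * e2,
        ])

    def product_flux(y):
        s1, e2 = y[:, 1], y[:, 3]
        s1c = np.clip(s1, 0.0, None)
        return kcat2 * e2 * s1c / (Km2 + s1c)

    model._rhs = rhs
    model._product_flux = product_flux
    return model


def _build_glucaric(kin, lam, v_in, hill_n, tox) -> PathwayModel:
    spec = RegulatorySpec(
        ligands=("MI",),
        promoters=(Promoter("pIno1", ("Ino1",)), Promoter("pMIOX", ("MIOX",))),
        position_map={("MI", "pIno1"): "upstream", ("MI", "pMIOX"): "downstream"},
    )
    names = {
        ((0, 0),): "open_loop",
        ((-1, 0),): "upstream_repression",
        ((0, 1),): "downstream_activation",
        ((-1, 1),): "dual_control",
    }
    model = PathwayModel(
        model_id="glucaric_acid",
        metabolites=("g6p", "MI", "GA"),
        proteins=("Ino1", "MIOX"),
        extra_states=(),
        kinetics=kin,
        dilution=lam,
        v_in=v_in,
        regulatory_spec=spec,
        pc_names=("k1", "theta1", "k2", "theta2"),
        pc_bounds=_KTH_BOUNDS * 2,
        pc_defaults=(5.0, 1.0, 5.0, 1.0),
        hill_n=hill_n,
        t_span=(0.0, 12.0),
        n_grid=121,
        default_cost_weights=(1.0, 0.1146),
        arch_names=names,
        provenance={
            "structure": "glucose-6-phosphate -> myo-inositol (Ino1) -> glucaric acid "
                         "(MIOX, allosterically activated by MI); MI exported; SuhB "
                         "not rate-limiting and lumped away",
            "parameters": "synthetic-nominal",
        },
    )
    layout = {"pIno1": (0, 1), "pMIOX": (2, 3)}
    model.promoter_params = lambda p_c, arch: _matrix_promoter_params(model, p_c, arch, layout)

    kcat_I, Km_I = kin["kcat_Ino1"], kin["Km_Ino1"]
    k_nat, k_exp, k_out = kin["k_nat"], kin["k_export"], kin["k_out"]
    recipe_cache: dict = {}

    def rhs(t, x, arch, p_c):
        rec = recipe_cache.get(id(arch))
        if rec is None:
            rec = recipe_cache[id(arch)] = _compiled_control(model, arch, layout)
        g6p, mi, ga, e_i, e_m = x
        g6pc, mic = max(g6p, 0.0), max(mi, 0.0)
        v_i = kcat_I * e_i * g6pc / (Km_I + g6pc)
        v_m = (
            model.kinetics["Vm_MIOX"] * e_m * mic / (model.kinetics["km_MIOX"] + mic)
            * (1.0 + model.kinetics["a_MIOX"] * mic / (model.kinetics["ka_MIOX"] + mic))
        )
        u = _promoter_rates(x, p_c, rec, model.hill_n)
        lam_ = model.dilution
        return np.array([
            model.v_in - k_nat * g6p - v_i,
            v_i - v_m - k_exp * mi,
            v_m - k_out * ga,
            u[0] - lam_ * e_i,
            u[1] - lam_ * e_m,
        ])

    def product_flux(y):
        mi = np.clip(y[:, 1], 0.0, None)
        e_m = y[:, 4]
        return (
            model.kinetics["Vm_MIOX"] * e_m * mi / (model.kinetics["km_MIOX"] + mi)
            * (1.0 + model.kinetics["a_MIOX"] * mi / (model.kinetics["ka_MIOX"] + mi))
        )

    model._rhs = rhs
    model._product_flux = product_flux
    return model


def _build_fatty(kin, lam, v_in, hill_n, tox) -> PathwayModel:
    # One metabolite (fatty acid), thioesterase, and a co-expressed repressor.
    # Architectures switch whole expression functions (categorical encoding):
    #   open_loop: constitutive; NML: FA-responsive TF represses the enzyme;
    #   NGL: co-expressed repressor represses its own promoter; LNML: both.
    model = PathwayModel(
        model_id="fatty_acid",
        metabolites=("FA",),
        proteins=("TesA", "Rep"),
        extra_states=(),
        kinetics=kin,
        dilution=lam,
        v_in=v_in,
        regulatory_spec=None,
        pc_names=("k", "theta"),
        pc_bounds=((1e-3, 15.0), (1e-2, 10.0)),
        pc_defaults=(5.0, 1.0),
        hill_n=hill_n,
        default_cost_weights=(1.0, 0.1217),
        categorical_archs=("open_loop", "NGL", "NML", "LNML"),
        provenance={
            "structure": "thioesterase releasing fatty acid from a constant acyl-ACP "
                         "pool; repressor co-expressed on the enzyme promoter",
            "parameters": "synthetic-nominal",
        },
    )
    k_syn, lam_s, theta_r = kin["k_syn"], kin["lambda_s"], kin["theta_r"]

    def expression(label, s, r, k, theta, n):
        u = k
        if label in ("NML", "LNML"):
            u *= 1.0 / (1.0 + _hill_terms(s, theta, n))
        if label in ("NGL", "LNML"):
            u *= 1.0 / (1.0 + _hill_terms(r, theta_r, n))
        return u

    def rhs(t, x, arch, p_c):
        s, e, r = x
        label = arch.categorical_label
        u = expression(label, s, r, p_c[0], p_c[1], model.hill_n)
        lam_ = model.dilution
        coexpr = u if label in ("NGL", "LNML") else 0.0
        return np.array([
            k_syn * e - lam_s * s,
            u - lam_ * e,
            coexpr - lam_ * r,
        ])

    def product_flux(y):
        return k_syn * y[:, 1]

    model._rhs = rhs
    model._product_flux = product_flux
    model._expression = expression
    return model


def _build_pas(kin, lam, v_in, hill_n, tox) -> PathwayModel:
    # 23 states: 7 metabolites + 4 mRNAs + 6 unfolded + 6 folded proteins.
    # Substrate S -> (PapA, PapB, PapC on the papABC operon) -> p-AF -> (E) ->
    # p-ACA -> efflux pump -> extracellular product P. LAAO (constitutive unit)
    # drains p-AF and releases H2O2; p-AF also leaks from the cell. A toxicity
    # factor tau scales all synthesis/degradation/folding rates.
    spec = RegulatorySpec(
        ligands=("pAF", "pACA"),
        promoters=(
            Promoter("pABC", ("PapA", "PapB", "PapC")),
            Promoter("pE", ("EnzE",)),
            Promoter("pPump", ("Pump",)),
        ),
        position_map={
            ("pAF", "pABC"): "upstream",
            ("pACA", "pABC"): "upstream",
            ("pAF", "pE"): "downstream",
            ("pACA", "pE"): "upstream",
            ("pAF", "pPump"): "downstream",
            ("pACA", "pPump"): "downstream",
        },
    )
    metabolites = ("S", "M1", "M2", "pAF", "pACA", "H2O2", "P")
    mrnas = ("m_ABC", "m_E", "m_Pump", "m_LAAO")
    unfolded = ("uPapA", "uPapB", "uPapC", "uEnzE", "uPump", "uLAAO")
    folded = ("PapA", "PapB", "PapC", "EnzE", "Pump", "LAAO")
    pc_names = (
        "b_ABC", "b_E", "b_Pump",
        "k_pAF_ABC", "theta_pAF_ABC", "k_pACA_ABC", "theta_pACA_ABC",
        "k_pAF_E", "theta_pAF_E", "k_pACA_E", "theta_pACA_E",
        "k_pAF_Pump", "theta_pAF_Pump", "k_pACA_Pump", "theta_pACA_Pump",
        "b_LAAO",
    )
    bounds = ((1e-3, 10.0),) * 3 + ((1e-3, 15.0), (1e-2, 5.0)) * 6 + ((1e-3, 1.0),)
    model = PathwayModel(
        model_id="p_aminostyrene",
        metabolites=metabolites,
        proteins=folded,
        extra_states=mrnas + unfolded,
        kinetics=kin,
        dilution=lam,
        v_in=v_in,
        regulatory_spec=spec,
        pc_names=pc_names,
        pc_bounds=bounds,
        pc_defaults=(1.0, 1.0, 1.0) + (1.0, 1.0) * 6 + (0.1,),
        hill_n=hill_n,
        toxicity=tox,
        default_cost_weights=(1.0, 0.0918),
        provenance={
            "structure": "papABC operon, LAAO side drain with H2O2 byproduct, "
                         "p-AF leak, cytotoxic p-ACA removed by an efflux pump; "
                         "mRNA and folding dynamics per transcription unit",
            "parameters": "synthetic-nominal",
        },
    )

    # promoter -> (k index, theta index) depends on the controlling ligand, so
    # the shared matrix layout helper does not apply; build params directly.
    pair_slot = {("pAF", "pABC"): 3, ("pACA", "pABC"): 5,
                 ("pAF", "pE"): 7, ("pACA", "pE"): 9,
                 ("pAF", "pPump"): 11, ("pACA", "pPump"): 13}
    basal_slot = {"pABC": 0, "pE": 1, "pPump": 2}

    def promoter_params(p_c, arch):
        p = model.validate_pc(p_c)
        out = {}
        for j, prom in enumerate(spec.promoters):
            ctrl = arch.controller_of(j)
            if ctrl is None:
                out[prom.name] = ConstitutiveParams(k0=p[basal_slot[prom.name]])
            else:
                lig = spec.ligands[ctrl[0]]
                i = pair_slot[(lig, prom.name)]
                out[prom.name] = DoseResponseParams(k=p[i], theta=p[i + 1], n=model.hill_n)
        return out

    model.promoter_params = promoter_params

    def compiled(arch):
        rec = []
        for j, prom in enumerate(spec.promoters):
            ctrl = arch.controller_of(j)
            if ctrl is None:
                rec.append((0, -1, basal_slot[prom.name], -1))
            else:
                lig_idx, sign = ctrl
                lig = spec.ligands[lig_idx]
                i = pair_slot[(lig, prom.name)]
                s_idx = model.state_names.index(lig)
                rec.append((sign, s_idx, i, i + 1))
        return rec

    recipe_cache: dict = {}
    kc = kin
    # translation unit membership: protein index -> mRNA index (within mRNA block)
    unit_of = (0, 0, 0, 1, 2, 3)  # PapA,B,C <- m_ABC; EnzE <- m_E; Pump <- m_Pump; LAAO <- m_LAAO

    def rhs(t, x, arch, p_c):
        rec = recipe_cache.get(id(arch))
        if rec is None:
            rec = recipe_cache[id(arch)] = compiled(arch)
        s = np.clip(x[:7], 0.0, None)
        m = x[7:11]
        u_prot = x[11:17]
        f_prot = x[17:23]
        S, M1, M2, pAF, pACA, H, P = s
        A, B, C, E, Pump, LAAO = np.clip(f_prot, 0.0, None)

        vA = kc["kcat_A"] * A * S / (kc["Km_A"] + S)
        vB = kc["kcat_B"] * B * M1 / (kc["Km_B"] + M1)
        vC = kc["kcat_C"] * C * M2 / (kc["Km_C"] + M2)
        vE = kc["kcat_E"] * E * pAF / (kc["Km_E"] + pAF)
        vL = kc["kcat_L"] * LAAO * pAF / (kc["Km_L"] + pAF)
        vP = kc["k_pump"] * Pump * pACA / (kc["Km_pump"] + pACA)

        tx = model.toxicity
        tau = max(1.0 / (1.0 + tx.t_l * vL + tx.t_a * pACA + tx.t_p * Pump), 1e-6)

        u_promoter = _promoter_rates(x, p_c, rec, model.hill_n)  # pABC, pE, pPump
        tx_rates = np.array([u_promoter[0], u_promoter[1], u_promoter[2], p_c[15]])

        lam_ = model.dilution
        dm = tau * tx_rates - kc["d_m"] * m
        du = np.empty(6)
        df = np.empty(6)
        for i in range(6):
            transl = tau * kc["k_tl"] * m[unit_of[i]]
            fold = tau * kc["k_fold"] * u_prot[i]
            du[i] = transl - fold - lam_ * u_prot[i]
            df[i] = fold - lam_ * f_prot[i] - tau * kc["d_p"] * f_prot[i]

        ds = np.array([
            model.v_in - kc["k_nat"] * S - vA,
            vA - vB,
            vB - vC,
            vC - vE - vL - kc["k_leak"] * pAF,
            vE - vP,
            vL - kc["k_H"] * H,
            vP,
        ])
        return np.concatenate([ds, dm, du, df])

    def product_flux(y):
        pACA = np.clip(y[:, 4], 0.0, None)
        pump = np.clip(y[:, 21], 0.0, None)
        return kc["k_pump"] * pump * pACA / (kc["Km_pump"] + pACA)

    model._rhs = rhs
    model._product_flux = product_flux
    return model


_NOMINAL: dict[str, dict] = {
    "toy": dict(
        kinetics=dict(k_nat=1.0, kcat1=10.0, Km1=1.0, kcat2=10.0, Km2=1.0),
        dilution=0.5, v_in=1.0,
        builder=_build_toy,
    ),
    "glucaric_acid": dict(
        # MIOX is the rate-limiting step (low Vm, activated by its precursor);
        # Ino1 is catalytically weak so meaningful flux needs high expression;
        # MI export makes transient MI excess a real loss. Under this card the
        # dual-control architecture is the strict optimum of the cost-benefit
        # loss, with each single loop clearly suboptimal.
        kinetics=dict(
            k_nat=1.0, kcat_Ino1=0.5, Km_Ino1=1.0,
            Vm_MIOX=0.1, km_MIOX=0.3, a_MIOX=4.0, ka_MIOX=0.3,
            k_export=1.5, k_out=1.0,
        ),
        dilution=0.5, v_in=1.0,
        builder=_build_glucaric,
    ),
    "fatty_acid": dict(
        kinetics=dict(k_syn=1.0, lambda_s=0.3, theta_r=1.0),
        dilution=0.5, v_in=0.0,
        builder=_build_fatty,
    ),
    "p_aminostyrene": dict(
        kinetics=dict(
            k_nat=1.0,
            kcat_A=10.0, Km_A=1.0, kcat_B=10.0, Km_B=1.0, kcat_C=10.0, Km_C=1.0,
            kcat_E=10.0, Km_E=1.0, kcat_L=5.0, Km_L=1.0,
            k_pump=10.0, Km_pump=1.0,
            k_leak=0.1, k_H=1.0,
            k_tl=10.0, d_m=10.0, k_fold=10.0, d_p=0.1,
        ),
        dilution=0.5, v_in=1.0,
        toxicity=ToxicityParams(t_l=0.01, t_a=1e-3, t_p=0.03),
        builder=_build_pas,
    ),
}


def build_model(model_id: str, overrides: Mapping[str, float] | None = None) -> PathwayModel:
    """Construct one of the four built-in pathway models, optionally overriding
    named kinetic/toxicity parameters, ``V_in``, ``lambda`` or ``hill_n``."""
    if model_id not in _NOMINAL:
        raise ConfigurationError(
            f"unknown model {model_id!r}; choose from {MODEL_IDS}"
        )
    card = _NOMINAL[model_id]
    kin = dict(card["kinetics"])
    lam, v_in, hill_n = card["dilution"], card["v_in"], 2.0
    tox: ToxicityParams = card.get("toxicity", ToxicityParams())
    if overrides:
        tox_kw = {"t_l": tox.t_l, "t_a": tox.t_a, "t_p": tox.t_p}
        for name, value in overrides.items():
            if name in kin:
                kin[name] = value
            elif name == "lambda":
                if value < 0:
                    raise ConfigurationError("lambda must be non-negative")
                lam = value
            elif name == "V_in":
                if value < 0:
                    raise ConfigurationError("V_in must be non-negative")
                v_in = value
            elif name == "hill_n":
                hill_n = value
            elif name in tox_kw:
                tox_kw[name] = value
            else:
                raise ConfigurationError(f"unknown parameter {name!r} for {model_id}")
        tox = ToxicityParams(**tox_kw)
    return card["builder"](KineticParams(**kin), lam, v_in, hill_n, tox)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    model: PathwayModel,
    arch: ArchitectureSpec,
    p_c: Sequence[float],
    t_span: tuple[float, float] | None = None,
    init: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    rtol: float = _DEFAULT_RTOL,
    atol: float = _DEFAULT_ATOL,
    method: str = "lsoda",
) -> SimulationResult:
    """Integrate the model for one design (arch, p_c).

    Heterologous protein (and mRNA) states start at zero unless ``init``
    provides a full state vector; metabolite initials default to the
    no-heterologous-enzyme steady state. Integration failures are reported via
    ``success=False`` (never raised) so optimization loops can penalize them.
    """
    p = model.validate_pc(p_c)
    if t_span is None:
        t_span = model.t_span
    if grid is None:
        grid = np.linspace(t_span[0], t_span[1], model.n_grid)
    if init is None:
        x0 = np.zeros(model.n_states)
        x0[: len(model.metabolites)] = steady_state_init(model)
    else:
        x0 = np.asarray(init, dtype=float)
        if x0.shape != (model.n_states,):
            raise ConfigurationError(
                f"init must have shape ({model.n_states},), got {x0.shape}"
            )

    try:
        if method == "lsoda":
            y, info = odeint(
                lambda x, t: model.rhs(t, x, arch, p),
                x0, grid, rtol=rtol, atol=atol, mxstep=10000, full_output=True,
            )
            ok = info["message"] == "Integration successful." and np.isfinite(y).all()
            msg = info["message"]
        else:
            sol = solve_ivp(
                lambda t, x: model.rhs(t, x, arch, p),
                t_span, x0, method="BDF", t_eval=grid, rtol=rtol, atol=atol,
            )
            y, ok, msg = sol.y.T, sol.success and np.isfinite(sol.y).all(), sol.message
    except Exception as exc:  # pragma: no cover - defensive
        return SimulationResult(
            t=np.asarray(grid), y=np.full((len(grid), model.n_states), np.nan),
            success=False, message=str(exc), state_names=model.state_names,
        )
    return SimulationResult(
        t=np.asarray(grid), y=y, success=bool(ok), message=str(msg),
        state_names=model.state_names,
    )


def steady_state_init(model: PathwayModel, tol: float = _SS_RTOL) -> np.ndarray:
    """Native-metabolite initial state: integrate with all heterologous protein
    states clamped at zero until max|ds/dt| / max(|s|, floor) < tol."""
    key = (id(model), tol)
    cached = getattr(model, "_ss_cache", None)
    if cached is not None and cached[0] == key:
        return cached[1].copy()

    n_m = len(model.metabolites)
    arch = model.architectures()[0]
    p = np.asarray(model.pc_defaults, dtype=float)
    zeros = np.zeros(model.n_states - n_m)

    def rhs_native(s, t):
        x = np.concatenate([s, zeros])
        return model.rhs(t, x, arch, p)[:n_m]

    s = np.zeros(n_m)
    t_elapsed, chunk = 0.0, 100.0
    while t_elapsed < _SS_HORIZON:
        ts = np.linspace(0, chunk, 11)
        s = odeint(rhs_native, s, ts, rtol=1e-10, atol=1e-12)[-1]
        t_elapsed += chunk
        resid = np.max(np.abs(rhs_native(s, 0.0)))
        scale = max(np.max(np.abs(s)), 1.0)
        if resid / scale < tol:
            model._ss_cache = (key, s.copy())
            return s
    raise RuntimeError(
        f"{model.model_id}: no native steady state within {_SS_HORIZON} h "
        f"(residual {resid:.3e}, scale {scale:.3e})"
    )
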