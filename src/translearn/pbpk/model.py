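"""Whole-body parent–metabolite PK model and its forward simulation.

Structure
---------
Seven compartments per compound: gut lumen (amount-only bookkeeping), gut
wall, liver, kidney, arterial plasma, venous plasma and a lumped rest-of-body
tissue.  Plasma circulates arterial → tissues → venous → arterial; the gut
wall drains into the liver (portal vein).  Tissue uptake is flow-limited by
default; a drug-specific endothelial permeability scale s ∈ (0,1] turns an
organ permeability-limited by letting only the fraction s of the perfusing
plasma equilibrate with tissue (outflow concentration
``(1-s)·C_in + s·C_tissue/Kp``), which conserves mass and reduces to the
flow limit at s = 1.  The gut-wall mucosa sits luminal of the endothelium
(it is the absorption pathway), so the barrier never applies there.

Active processes are Michaelis–Menten in the unbound plasma-equivalent
concentration of their source compartment, with organ-local Vmax =
kcat × expression.  Metabolism with a modelled product transfers mass
molar-to-molar into the product species in the same organ; without a product
it feeds the terminal-metabolism ledger.  Renal clearance (l/min/kg body
weight) filters arterial plasma into a cumulative urine ledger.

All amounts are µmol, internal time is minutes.  The right-hand side is
compiled to flat parameter arrays and evaluated through a jitted kernel so
that the population-inference layer can afford tens of thousands of solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

from .. import constants
from .types import (
    ConcentrationProfile,
    ConfigurationError,
    DoseEvent,
    DrugParams,
    Physiology,
    ValidationError,
    ORGANS,
    TISSUES,
)

I_LUMEN, I_GUT, I_LIVER, I_KIDNEY, I_ART, I_VEN, I_REST = range(7)
I_URINE, I_TERMINAL = 7, 8
N_SLOTS = 9  # 7 organs + urine ledger + terminal-metabolism ledger

#: Canonical topology of the transport proteins: expression organ →
#: (source compartment, destination compartment).  PGP/ABCB1 effluxes into
#: the gut lumen from gut wall and liver; OATP1B1 is sinusoidal uptake from
#: circulating plasma into liver tissue.
TRANSPORT_ROUTES = {
    "ABCB1": {"gut_wall": ("gut_wall", "gut_lumen"), "liver": ("liver", "gut_lumen")},
    "OATP1B1": {"liver": ("venous_plasma", "liver")},
}

_ORGAN_INDEX = {name: i for i, name in enumerate(ORGANS)}


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message echoes the parameter vector."""


def _rhs_core(
    y,
    dy,
    vol,
    kp,
    scale,
    ka,
    cl_renal,
    q_gut,
    q_ha,
    q_liver,
    q_kidney,
    q_rest,
    q_co,
    p_src,
    p_dst,
    p_vmax,
    p_km,
    p_fu_invvkp,
):
    ncomp = ka.shape[0]
    for ci in range(ncomp):
        b = ci * N_SLOTS
        c_art = y[b + I_ART] / vol[I_ART]
        c_ven = y[b + I_VEN] / vol[I_VEN]
        cp_gut = y[b + I_GUT] / (vol[I_GUT] * kp[ci, I_GUT])
        cp_liv = y[b + I_LIVER] / (vol[I_LIVER] * kp[ci, I_LIVER])
        cp_kid = y[b + I_KIDNEY] / (vol[I_KIDNEY] * kp[ci, I_KIDNEY])
        cp_rest = y[b + I_REST] / (vol[I_REST] * kp[ci, I_REST])
        s_liv = scale[ci, I_LIVER]
        s_kid = scale[ci, I_KIDNEY]
        s_rest = scale[ci, I_REST]

        # gut wall mucosa: flow-limited, portal outflow feeds the liver
        f_gut = q_gut * (c_art - cp_gut)
        c_liv_in = (q_ha * c_art + q_gut * cp_gut) / q_liver
        f_liv = q_liver * s_liv * (c_liv_in - cp_liv)
        c_liv_out = (1.0 - s_liv) * c_liv_in + s_liv * cp_liv
        f_kid = q_kidney * s_kid * (c_art - cp_kid)
        c_kid_out = (1.0 - s_kid) * c_art + s_kid * cp_kid
        f_rest = q_rest * s_rest * (c_art - cp_rest)
        c_rest_out = (1.0 - s_rest) * c_art + s_rest * cp_rest

        dy[b + I_GUT] = f_gut
        dy[b + I_LIVER] = f_liv
        dy[b + I_KIDNEY] = f_kid
        dy[b + I_REST] = f_rest
        dy[b + I_VEN] = (
            q_liver * c_liv_out + q_kidney * c_kid_out + q_rest * c_rest_out - q_co * c_ven
        )
        dy[b + I_ART] = q_co * (c_ven - c_art)
        dy[b + I_LUMEN] = 0.0
        dy[b + I_URINE] = 0.0
        dy[b + I_TERMINAL] = 0.0

        if ka[ci] > 0.0:
            lumen = y[b + I_LUMEN]
            if lumen < 0.0:
                lumen = 0.0
            absorbed = ka[ci] * lumen
            dy[b + I_LUMEN] -= absorbed
            dy[b + I_GUT] += absorbed
        if cl_renal[ci] > 0.0:
            ca = c_art
            if ca < 0.0:
                ca = 0.0
            filtered = cl_renal[ci] * ca
            dy[b + I_ART] -= filtered
            dy[b + I_URINE] += filtered

    for j in range(p_vmax.shape[0]):
        a = y[p_src[j]]
        if a < 0.0:
            a = 0.0
        cu = p_fu_invvkp[j] * a
        rate = p_vmax[j] * cu / (p_km[j] + cu)
        dy[p_src[j]] -= rate
        dy[p_dst[j]] += rate
    return dy


try:  # jitted kernel; the plain-python version above stays the reference
    from numba import njit

    _rhs_core_jit = njit(cache=False, fastmath=False)(_rhs_core)
except ImportError:  # pragma: no cover - numba is a soft dependency
    _rhs_core_jit = _rhs_core


@dataclass(frozen=True)
class _CompiledProcess:
    """Introspection record of one organ-local active-process instance."""

    protein: str
    kind: str
    compound: str
    source_organ: str
    dest: str  # organ name, "urine" or "terminal"
    vmax: float
    km: float


def partition_coefficient(drug: DrugParams, organ: str) -> float:
    """Tissue:plasma partition coefficient of the fixed lipoidal rule.

    ``Kp = 1 + f_lipid(organ) · 10**lipophilicity · fraction_unbound`` for
    perfused tissues; plasma pools and the lumen partition with 1.  Monotone
    in lipophilicity by construction.
    """
    if organ in ("arterial_plasma", "venous_plasma", "gut_lumen"):
        return 1.0
    return 1.0 + constants.F_LIPID[organ] * 10.0**drug.lipophilicity * drug.fraction_unbound


class PbpkModel:
    """Compiled ODE system for one individual and one parent–metabolite pair."""

    def __init__(self, physiology: Physiology, parent: DrugParams, metabolite: DrugParams):
        self.physiology = physiology
        self.compounds = (parent, metabolite)
        self.names = (parent.name, metabolite.name)
        self._name_index = {n: i for i, n in enumerate(self.names)}
        self.n_state = len(self.compounds) * N_SLOTS
        self._compile()

    # -- construction -----------------------------------------------------

    def _compile(self) -> None:
        phys = self.physiology
        self.volumes = np.array([phys.organ_volumes[o] for o in ORGANS])
        q = phys.organ_flows
        self.q_gut = q["gut_wall"]
        self.q_ha = q["liver"]
        self.q_liver = self.q_gut + self.q_ha
        self.q_kidney = q["kidney"]
        self.q_rest = q["rest"]
        self.q_co = q["cardiac_output"]

        ncomp = len(self.compounds)
        self.kp = np.ones((ncomp, 7))
        self.scale = np.ones((ncomp, 7))  # endothelial scale per organ
        self.ka = np.zeros(ncomp)  # 1/min, oral absorption
        self.cl_renal = np.zeros(ncomp)  # l/min, linear renal clearance
        for ci, drug in enumerate(self.compounds):
            for organ in TISSUES:
                self.kp[ci, _ORGAN_INDEX[organ]] = partition_coefficient(drug, organ)
            for organ, s in drug.endothelial_permeability_scale.items():
                if organ == "gut_wall":
                    continue  # mucosa is luminal of the endothelial barrier
                if organ in _ORGAN_INDEX:
                    self.scale[ci, _ORGAN_INDEX[organ]] = s
            if drug.intestinal_permeability is not None:
                self.ka[ci] = (
                    drug.intestinal_permeability * constants.EFFECTIVE_AREA_CONSTANT_PER_CM
                )
            if drug.renal_clearance_specific is not None:
                self.cl_renal[ci] = drug.renal_clearance_specific * phys.body_weight

        records: list[_CompiledProcess] = []
        src, dst, vmax, km, fu_invvkp = [], [], [], [], []
        for ci, drug in enumerate(self.compounds):
            for proc in drug.processes:
                for rec, arrs in self._compile_process(ci, drug, proc):
                    records.append(rec)
                    s_i, d_i, v_i, k_i, f_i = arrs
                    src.append(s_i)
                    dst.append(d_i)
                    vmax.append(v_i)
                    km.append(k_i)
                    fu_invvkp.append(f_i)
        self.process_records = tuple(records)
        self._p_src = np.array(src, dtype=np.int64)
        self._p_dst = np.array(dst, dtype=np.int64)
        self._p_vmax = np.array(vmax, dtype=float)
        self._p_km = np.array(km, dtype=float)
        self._p_fu_invvkp = np.array(fu_invvkp, dtype=float)

    @property
    def active_process_names(self) -> set[str]:
        return {r.protein for r in self.process_records}

    def _expression_sites(self, protein: str) -> list[tuple[str, float]]:
        sites = [
            (organ, e)
            for (p, organ), e in self.physiology.expression.items()
            if p == protein and e > 0
        ]
        if not sites:
            raise ConfigurationError(
                f"no expression entry for protein {protein!r} in any organ of this physiology"
            )
        return sorted(sites)

    def _compile_process(self, ci: int, drug: DrugParams, proc):
        base = ci * N_SLOTS
        out = []
        sites = self._expression_sites(proc.protein)
        if proc.kind == "metabolism":
            dest_ci = self._name_index.get(proc.product, -1) if proc.product else -1
            if proc.product and dest_ci < 0:
                raise ConfigurationError(
                    f"metabolism product {proc.product!r} is not a modelled compound"
                )
            for organ, expr in sites:
                oi = _ORGAN_INDEX[organ]
                dst_abs = dest_ci * N_SLOTS + oi if dest_ci >= 0 else base + I_TERMINAL
                out.append(
                    (
                        _CompiledProcess(
                            proc.protein,
                            proc.kind,
                            drug.name,
                            organ,
                            proc.product if dest_ci >= 0 else "terminal",
                            proc.kcat * expr,
                            proc.km,
                        ),
                        (
                            base + oi,
                            dst_abs,
                            proc.kcat * expr,
                            proc.km,
                            drug.fraction_unbound / (self.volumes[oi] * self.kp[ci, oi]),
                        ),
                    )
                )
        elif proc.kind == "transport":
            routes = TRANSPORT_ROUTES.get(proc.protein)
            if routes is None:
                raise ConfigurationError(
                    f"no transport topology defined for protein {proc.protein!r}"
                )
            for organ, expr in sites:
                route = routes.get(organ)
                if route is None:
                    continue  # expression site without a modelled route
                s_name, d_name = route
                si, di = _ORGAN_INDEX[s_name], _ORGAN_INDEX[d_name]
                out.append(
                    (
                        _CompiledProcess(
                            proc.protein,
                            proc.kind,
                            drug.name,
                            s_name,
                            d_name,
                            proc.kcat * expr,
                            proc.km,
                        ),
                        (
                            base + si,
                            base + di,
                            proc.kcat * expr,
                            proc.km,
                            drug.fraction_unbound / (self.volumes[si] * self.kp[ci, si]),
                        ),
                    )
                )
        else:  # renal_excretion: kidney-local saturable excretion into urine
            for organ, expr in sites:
                oi = _ORGAN_INDEX[organ]
                out.append(
                    (
                        _CompiledProcess(
                            proc.protein, proc.kind, drug.name, organ, "urine",
                            proc.kcat * expr, proc.km,
                        ),
                        (
                            base + oi,
                            base + I_URINE,
                            proc.kcat * expr,
                            proc.km,
                            drug.fraction_unbound / (self.volumes[oi] * self.kp[ci, oi]),
                        ),
                    )
                )
        return out

    # -- dynamics ----------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """dy/dt in µmol/min (time in minutes)."""
        dy = np.empty_like(y)
        _rhs_core_jit(
            y,
            dy,
            self.volumes,
            self.kp,
            self.scale,
            self.ka,
            self.cl_renal,
            self.q_gut,
            self.q_ha,
            self.q_liver,
            self.q_kidney,
            self.q_rest,
            self.q_co,
            self._p_src,
            self._p_dst,
            self._p_vmax,
            self._p_km,
            self._p_fu_invvkp,
        )
        return dy

    # -- simulation --------------------------------------------------------

    def molar_amount(self, dose: DoseEvent) -> float:
        ci = self._name_index.get(dose.compound)
        if ci is None:
            raise ValidationError(f"dose names unknown compound {dose.compound!r}")
        mw = self.compounds[ci].molecular_weight
        return dose.amount * 1000.0 / mw  # mg → µmol

    def solve(
        self,
        doses: Sequence[DoseEvent],
        output_times: Sequence[float],
        individual_id: str = "mean",
    ) -> "SimulationResult":
        """Integrate the system and sample it on ``output_times`` (hours)."""
        t_out = np.unique(np.asarray(output_times, dtype=float))
        if t_out.size == 0 or np.any(t_out < 0):
            raise ValidationError("output times must be non-negative and non-empty")
        t_out_min = t_out * 60.0
        events = sorted(doses, key=lambda d: d.time)
        for d in events:
            if d.compound not in self._name_index:
                raise ValidationError(f"dose names unknown compound {d.compound!r}")
        y = np.zeros(self.n_state)
        y_out = np.zeros((self.n_state, t_out.size))
        args = (
            self.volumes,
            self.kp,
            self.scale,
            self.ka,
            self.cl_renal,
            self.q_gut,
            self.q_ha,
            self.q_liver,
            self.q_kidney,
            self.q_rest,
            self.q_co,
            self._p_src,
            self._p_dst,
            self._p_vmax,
            self._p_km,
            self._p_fu_invvkp,
        )
        dy_buf = np.empty(self.n_state)

        def f(y_, t_):
            return _rhs_core_jit(y_, dy_buf, *args)

        for d in events:
            if d.time == 0.0:
                y[self._name_index[d.compound] * N_SLOTS + I_LUMEN] += self.molar_amount(d)
        mask0 = t_out_min <= 0.0
        y_out[:, mask0] = y[:, None]
        breakpoints = sorted({t_out_min[-1], *[d.time * 60.0 for d in events if d.time > 0]})
        t_now = 0.0
        for t_next in breakpoints:
            if t_next <= t_now:
                continue
            sample = (t_out_min > t_now) & (t_out_min <= t_next)
            t_grid = np.concatenate([[t_now], t_out_min[sample]])
            if t_grid[-1] < t_next:
                t_grid = np.concatenate([t_grid, [t_next]])
            sol, info = odeint(
                f,
                y,
                t_grid,
                rtol=constants.SOLVER_RTOL,
                atol=constants.SOLVER_ATOL,
                mxstep=20000,
                full_output=True,
            )
            if info["message"] != "Integration successful.":
                raise IntegrationError(
                    f"solver failed in [{t_now:.3f}, {t_next:.3f}] min: "
                    f"{info['message']}; state={y.tolist()}"
                )
            n_sample = int(sample.sum())
            y_out[:, sample] = sol[1 : 1 + n_sample].T
            y = sol[-1].copy()
            t_now = t_next
            for d in events:
                if d.time > 0 and abs(d.time * 60.0 - t_next) < 1e-12:
                    y[self._name_index[d.compound] * N_SLOTS + I_LUMEN] += self.molar_amount(d)
        return SimulationResult(
            model=self,
            individual_id=individual_id,
            times_h=t_out,
            states=y_out,
            doses=tuple(events),
        )


@dataclass(frozen=True)
class SimulationResult:
    """Full state trajectory sampled at the requested output times."""

    model: PbpkModel
    individual_id: str
    times_h: np.ndarray
    states: np.ndarray  # (n_state, n_times), µmol
    doses: tuple[DoseEvent, ...]

    def amounts(self, compound: str) -> np.ndarray:
        ci = self.model._name_index[compound]
        return self.states[ci * N_SLOTS : (ci + 1) * N_SLOTS]

    def venous_concentration(self, compound: str) -> np.ndarray:
        ci = self.model._name_index[compound]
        conc = self.states[ci * N_SLOTS + I_VEN] / self.model.volumes[I_VEN]
        # solver round-off can leave ~atol-scale negatives
        return np.where(conc < 0, 0.0, conc)

    def profiles(self) -> list[ConcentrationProfile]:
        return [
            ConcentrationProfile(
                individual_id=self.individual_id,
                compound=name,
                times=self.times_h,
                concentrations=self.venous_concentration(name),
            )
            for name in self.model.names
        ]


def build_model(
    physiology: Physiology, parent: DrugParams, metabolite: DrugParams
) -> PbpkModel:
    """Assemble the compiled ODE system for one individual and drug pair."""
    return PbpkModel(physiology, parent, metabolite)


def simulate(
    model: PbpkModel,
    doses: Sequence[DoseEvent],
    output_times: Sequence[float],
    individual_id: str = "mean",
) -> list[ConcentrationProfile]:
    """Venous-plasma profiles (parent and metabolite) at ``output_times`` (h)."""
    return model.solve(doses, output_times, individual_id=individual_id).profiles()


def mass_balance(model: PbpkModel, solution: SimulationResult) -> dict:
    """Molar mass-balance ledger of a simulated trajectory.

    At every sampled time, the amounts in all compartments of both compounds
    plus the cumulative urine and terminal-metabolism ledgers must equal the
    molar dose administered up to that time (metabolite mass is counted on
    the shared molar basis, so parent→metabolite conversion is 1:1).
    """
    dosed = np.zeros_like(solution.times_h)
    for d in solution.doses:
        # samples at the exact event time are taken pre-dose (except t = 0,
        # where the initial state already contains the dose)
        given = (
            solution.times_h >= 0.0 if d.time == 0.0 else solution.times_h > d.time
        )
        dosed += np.where(given, model.molar_amount(d), 0.0)
    total = solution.states.sum(axis=0)
    scale = max(float(dosed.max()), 1e-30)
    rel_error = np.abs(total - dosed) / scale
    max_rel_error = float(rel_error.max())
    ledger = {
        "times_h": solution.times_h,
        "total_in_system": total,
        "dosed": dosed,
        "max_rel_error": max_rel_error,
        "closed": bool(max_rel_error <= constants.MASS_BALANCE_RTOL),
        "urine": {
            name: solution.states[ci * N_SLOTS + I_URINE]
            for ci, name in enumerate(model.names)
        },
        "terminal_metabolism": {
            name: solution.states[ci * N_SLOTS + I_TERMINAL]
            for ci, name in enumerate(model.names)
        },
    }
    if not ledger["closed"]:
        worst = int(np.argmax(rel_error))
        ledger["leak_report"] = (
            f"mass balance open by {max_rel_error:.3e} (relative) at "
            f"t={solution.times_h[worst]:.3f} h"
        )
    return ledger
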