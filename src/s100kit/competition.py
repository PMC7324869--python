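"""Ca²⁺-dependent S100A1 / actin competition for the titin PEVK segment.

S100A1 cycles through three Ca²⁺ states — apo, half-saturated (Ca²⁺ at the
high-affinity canonical EF-hand only) and fully-saturated (both the
canonical and the low-affinity pseudo EF-hand occupied).  Each state can
bind a PEVK peptide (P) with its own dissociation constant (Kd1, Kd2, Kd2′),
competing with the actin–PEVK association (A + P ⇌ AP, Kd K_AP) that
underlies titin-based passive tension.  Free Ca²⁺ is clamped at a stated
pCa (buffered assay); Ca²⁺ taken up by S100A1 is not depleted.

Only independent constants are parameterised: Ca²⁺ binding of free S100A1
(Kd_cEF, Kd_pEF) and per-state peptide binding.  The Ca²⁺ affinities of
peptide-bound states then follow from closing the thermodynamic cycles
(Wegscheider consistency), so detailed balance holds by construction.

The map from simulation to experiment is the multiplicative calibration
λ = exp((ΔG_expt − ΔG_calc)/RT) applied to computed dissociation constants,
and post-translational modification (C85 glutathionylation) rescales the
Ca²⁺-loaded Kds by λ·exp((ΔG_mod − ΔG_WT)/RT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ThermoParams",
    "CaBindingParams",
    "PeptideAffinities",
    "SystemTotals",
    "EquilibriumState",
    "Calibration",
    "FitResult",
    "dg_from_kd",
    "kd_from_dg",
    "calibrate_lambda",
    "ptm_scale_factor",
    "ca_state_fractions",
    "free_ca_from_pca",
    "solve_equilibrium",
    "dose_response",
    "fit_affinities",
    "predict_ptm_curves",
]


@dataclass(frozen=True)
class ThermoParams:
    """RT (kcal/mol) and the standard concentration for ΔG↔Kd maps.

    RT defaults to 0.593 kcal/mol (≈298 K), the value consistent with the
    printed calibration arithmetic; the WHAM module uses its own 300 K RT.
    """

    rt: float = 0.593
    c_standard_uM: float = 1.0e6       # 1 M in µM

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("RT must be positive")


@dataclass(frozen=True)
class CaBindingParams:
    """Sequential Ca²⁺ dissociation constants of the two EF-hands (µM)."""

    kd_cef_uM: float = 27.0
    kd_pef_uM: float = 250.0

    def __post_init__(self) -> None:
        if self.kd_cef_uM <= 0 or self.kd_pef_uM <= 0:
            raise ValueError("Ca dissociation constants must be positive")


@dataclass(frozen=True)
class PeptideAffinities:
    """Per-Ca-state PEVK dissociation constants (µM) with enable flags.

    Model variant 2 (default) lets all three states bind; variant 1
    disables the half-saturated state (``half_binds=False``).
    """

    kd1_uM: float = 0.52      # apo S100A1 · P
    kd2_uM: float = 0.13      # Ca·S100A1 · P
    kd2p_uM: float = 0.03     # 2Ca·S100A1 · P
    apo_binds: bool = True
    half_binds: bool = True
    full_binds: bool = True

    def __post_init__(self) -> None:
        if min(self.kd1_uM, self.kd2_uM, self.kd2p_uM) <= 0:
            raise ValueError("dissociation constants must be positive")

    def scaled(self, factor: float) -> "PeptideAffinities":
        """Rescale the Ca²⁺-loaded constants (Kd2, Kd2′) by ``factor``."""
        return replace(self, kd2_uM=self.kd2_uM * factor,
                       kd2p_uM=self.kd2p_uM * factor)


@dataclass(frozen=True)
class SystemTotals:
    """Total concentrations (µM) with Ca²⁺ set via pCa.

    With ``ca_depleted=False`` (default) the *free* Ca²⁺ is clamped at
    10^(6−pCa) µM (buffered assay).  With ``ca_depleted=True`` that same
    amount is the *total* Ca²⁺ and the free level is solved together with
    the other species — relevant when the protein concentration is
    comparable to the Ca²⁺ pool, as in dose–response assays run without a
    Ca²⁺ buffer.
    """

    s100_uM: float
    actin_uM: float
    pevk_uM: float
    pca: float = 7.0
    ca_depleted: bool = False

    def __post_init__(self) -> None:
        if min(self.s100_uM, self.actin_uM, self.pevk_uM) < 0:
            raise ValueError("totals must be non-negative")
        if not np.isfinite(self.pca):
            raise ValueError("pCa must be finite")


def free_ca_from_pca(pca: float) -> float:
    """Free Ca²⁺ (µM) from pCa = −log10([Ca²⁺]/M)."""
    return 10.0 ** (6.0 - pca)


@dataclass
class EquilibriumState:
    """Solved species concentrations (µM) of the competition scheme."""

    s: float          # apo S100A1, free
    ca_s: float       # half-saturated, free
    ca2_s: float      # fully-saturated, free
    a: float          # free actin
    p: float          # free PEVK
    ap: float         # actin·PEVK
    s_p: float        # apo S100A1·PEVK
    ca_s_p: float
    ca2_s_p: float
    totals: SystemTotals | None = None
    ca_free_uM: float | None = None

    @property
    def f_ap(self) -> float:
        """Fraction of total PEVK bound to actin."""
        if self.totals is None or self.totals.pevk_uM == 0:
            return 0.0
        return self.ap / self.totals.pevk_uM

    def species(self) -> dict[str, float]:
        return {"S": self.s, "Ca.S": self.ca_s, "2Ca.S": self.ca2_s,
                "A": self.a, "P": self.p, "AP": self.ap,
                "S.P": self.s_p, "Ca.S.P": self.ca_s_p, "2Ca.S.P": self.ca2_s_p}


@dataclass(frozen=True)
class Calibration:
    """λ scale from computed to experimental dissociation constants."""

    dg_expt: float = -6.5     # kcal/mol
    dg_calc: float = -9.5
    thermo: ThermoParams = field(default_factory=ThermoParams)

    @property
    def lam(self) -> float:
        return float(np.exp((self.dg_expt - self.dg_calc) / self.thermo.rt))


def dg_from_kd(kd_uM: float, thermo: ThermoParams | None = None) -> float:
    """Binding free energy ΔG = RT ln(Kd/c°) in kcal/mol."""
    thermo = thermo or ThermoParams()
    if kd_uM <= 0:
        raise ValueError("Kd must be positive")
    return float(thermo.rt * np.log(kd_uM / thermo.c_standard_uM))


def kd_from_dg(dg: float, thermo: ThermoParams | None = None) -> float:
    """Inverse of :func:`dg_from_kd`: Kd (µM) from ΔG (kcal/mol)."""
    thermo = thermo or ThermoParams()
    return float(thermo.c_standard_uM * np.exp(dg / thermo.rt))


def calibrate_lambda(dg_expt: float = -6.5, dg_calc: float = -9.5,
                     thermo: ThermoParams | None = None) -> Calibration:
    """Calibration λ = exp((ΔG_expt − ΔG_calc)/RT); K_expt = λ·K_calc."""
    if not (np.isfinite(dg_expt) and np.isfinite(dg_calc)):
        raise ValueError("free energies must be finite")
    return Calibration(dg_expt, dg_calc, thermo or ThermoParams())


def ptm_scale_factor(dg_mod: float, dg_wt: float,
                     calibration: Calibration | None = None,
                     thermo: ThermoParams | None = None) -> float:
    """Multiplicative factor on Kd after a PTM: λ·exp((ΔG_mod − ΔG_WT)/RT).

    Applied to the Ca²⁺-loaded constants Kd2 and Kd2′; a factor below one
    means tighter binding of the modified protein.
    """
    calibration = calibration or calibrate_lambda()
    thermo = thermo or calibration.thermo
    return float(calibration.lam * np.exp((dg_mod - dg_wt) / thermo.rt))


def ca_state_fractions(ca_free_uM: float,
                       ca_params: CaBindingParams | None = None
                       ) -> tuple[float, float, float]:
    """Population fractions (apo, half, full) of S100A1 at clamped free Ca²⁺.

    Sequential two-site binding: weights {1, c/Kd_cEF, c²/(Kd_cEF·Kd_pEF)}.
    """
    if ca_free_uM < 0:
        raise ValueError("free Ca must be non-negative")
    ca_params = ca_params or CaBindingParams()
    w1 = ca_free_uM / ca_params.kd_cef_uM
    w2 = w1 * ca_free_uM / ca_params.kd_pef_uM
    z = 1.0 + w1 + w2
    return (1.0 / z, w1 / z, w2 / z)


def _state_weights(ca_free_uM: float, ca_params: CaBindingParams):
    w1 = ca_free_uM / ca_params.kd_cef_uM
    w2 = w1 * ca_free_uM / ca_params.kd_pef_uM
    return 1.0, w1, w2


def _binding_coeff(ca_free_uM: float, ca_params: CaBindingParams,
                   affinities: PeptideAffinities) -> tuple[float, float]:
    """(Q, B): free-S100 partition sum and summed P-binding coefficient.

    Free S100 totals s·Q over Ca states; peptide-bound S100 totals s·p·B.
    """
    w0, w1, w2 = _state_weights(ca_free_uM, ca_params)
    q = w0 + w1 + w2
    b = 0.0
    if affinities.apo_binds:
        b += w0 / affinities.kd1_uM
    if affinities.half_binds:
        b += w1 / affinities.kd2_uM
    if affinities.full_binds:
        b += w2 / affinities.kd2p_uM
    return q, b


def solve_equilibrium(totals: SystemTotals,
                      ca_params: CaBindingParams | None = None,
                      affinities: PeptideAffinities | None = None,
                      k_ap_uM: float = 0.5,
                      tol: float = 1e-12, max_iter: int = 200) -> EquilibriumState:
    """Unique positive root of the mass-action competition scheme.

    Damped Newton iteration on the log free concentrations of the three
    conserved components (apo S100A1, actin, PEVK); working in log space
    keeps every species positive and the conservation system has a single
    root there.  With ``totals.ca_depleted`` the free Ca²⁺ is solved as
    well, by bracketing its own conservation residual (monotone in free
    Ca²⁺) around the inner Newton solve.  Conservation and every Kd
    relation hold to better than 1e−9 relative in the returned state (the
    solver raises with the residual if the ``tol`` target is not met).
    """
    ca_params = ca_params or CaBindingParams()
    affinities = affinities or PeptideAffinities()
    if k_ap_uM <= 0:
        raise ValueError("K_AP must be positive")
    if totals.ca_depleted:
        return _solve_depleted(totals, ca_params, affinities, k_ap_uM, tol,
                               max_iter)
    c = free_ca_from_pca(totals.pca)
    w0, w1, w2 = _state_weights(c, ca_params)
    q, b = _binding_coeff(c, ca_params, affinities)
    s_t, a_t, p_t = totals.s100_uM, totals.actin_uM, totals.pevk_uM

    # components with zero total are eliminated (free concentration zero)
    active = [k for k, t in enumerate((s_t, a_t, p_t)) if t > 0]
    x = np.array([np.log(t / 2.0) for t in (s_t, a_t, p_t) if t > 0])

    def species_from(xa: np.ndarray) -> tuple[float, float, float]:
        vals = {k: np.exp(v) for k, v in zip(active, xa)}
        return vals.get(0, 0.0), vals.get(1, 0.0), vals.get(2, 0.0)

    def residuals_jac(xa: np.ndarray):
        s, a, p = species_from(xa)
        f_full = np.array([
            s * (q + p * b) - s_t,
            a * (1.0 + p / k_ap_uM) - a_t,
            p + a * p / k_ap_uM + s * p * b - p_t,
        ])
        # Jacobian wrt log free concentrations
        j_full = np.array([
            [s * (q + p * b), 0.0, s * p * b],
            [0.0, a * (1.0 + p / k_ap_uM), a * p / k_ap_uM],
            [s * p * b, a * p / k_ap_uM, p + a * p / k_ap_uM + s * p * b],
        ])
        return f_full[active], j_full[np.ix_(active, active)]

    scale = np.array([max(t, 1.0) for t in (s_t, a_t, p_t)])[active]
    residual = np.inf
    if active:
        for _ in range(max_iter):
            f, j = residuals_jac(x)
            residual = float(np.max(np.abs(f) / scale))
            if residual < tol:
                break
            step = np.linalg.solve(j, -f)
            step = np.clip(step, -2.0, 2.0)     # damping in log space
            x = x + step
        else:
            f, _ = residuals_jac(x)
            residual = float(np.max(np.abs(f) / scale))
        if residual >= max(tol, 1e-9):
            raise RuntimeError(f"equilibrium solver did not converge "
                               f"(relative residual {residual:.3e})")
    s, a, p = species_from(x) if active else (0.0, 0.0, 0.0)
    state = EquilibriumState(
        s=s * w0, ca_s=s * w1, ca2_s=s * w2,
        a=a, p=p, ap=a * p / k_ap_uM,
        s_p=s * w0 * p / affinities.kd1_uM if affinities.apo_binds else 0.0,
        ca_s_p=s * w1 * p / affinities.kd2_uM if affinities.half_binds else 0.0,
        ca2_s_p=s * w2 * p / affinities.kd2p_uM if affinities.full_binds else 0.0,
        totals=totals,
        ca_free_uM=c,
    )
    return state


def _solve_depleted(totals: SystemTotals, ca_params: CaBindingParams,
                    affinities: PeptideAffinities, k_ap_uM: float,
                    tol: float, max_iter: int) -> EquilibriumState:
    """Outer solve of the Ca²⁺ conservation with inner clamped solves.

    Total Ca²⁺ is 10^(6−pCa) µM; bound Ca²⁺ (one per half-saturated, two
    per fully-saturated S100A1, peptide-bound or not) grows monotonically
    with the free level, so the residual is bracketed on [0, Ca_T].
    """
    from scipy.optimize import brentq

    ca_total = free_ca_from_pca(totals.pca)

    def clamped_at(c_free: float) -> EquilibriumState:
        eff_pca = 6.0 - np.log10(max(c_free, 1e-300))
        inner = replace(totals, pca=eff_pca, ca_depleted=False)
        return solve_equilibrium(inner, ca_params, affinities, k_ap_uM,
                                 tol, max_iter)

    def bound_ca(state: EquilibriumState) -> float:
        return (state.ca_s + 2.0 * state.ca2_s
                + state.ca_s_p + 2.0 * state.ca2_s_p)

    if ca_total == 0 or totals.s100_uM == 0:
        state = clamped_at(ca_total)
        free_c = ca_total
    else:
        def residual(c_free: float) -> float:
            return c_free + bound_ca(clamped_at(c_free)) - ca_total

        free_c = brentq(residual, 0.0, ca_total, xtol=1e-16 * max(ca_total, 1.0),
                        rtol=8.9e-16)
        state = clamped_at(free_c)
    return EquilibriumState(state.s, state.ca_s, state.ca2_s, state.a,
                            state.p, state.ap, state.s_p, state.ca_s_p,
                            state.ca2_s_p, totals=totals, ca_free_uM=free_c)


def dose_response(s100_grid_uM: np.ndarray, actin_uM: float, pevk_uM: float,
                  pca: float, ca_params: CaBindingParams | None = None,
                  affinities: PeptideAffinities | None = None,
                  k_ap_uM: float = 0.5, ca_depleted: bool = False
                  ) -> pd.DataFrame:
    """f_AP vs total S100A1 at one clamped pCa.

    Returns a frame (s100_total_uM, pCa, f_AP, f_AP_rel) where ``f_AP_rel``
    is normalised to the S100A1-free baseline.
    """
    grid = np.asarray(s100_grid_uM, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    baseline = solve_equilibrium(
        SystemTotals(0.0, actin_uM, pevk_uM, pca, ca_depleted),
        ca_params, affinities, k_ap_uM).f_ap
    rows = []
    for s_t in grid:
        st = solve_equilibrium(
            SystemTotals(float(s_t), actin_uM, pevk_uM, pca, ca_depleted),
            ca_params, affinities, k_ap_uM)
        rows.append({"s100_total_uM": float(s_t), "pCa": pca, "f_AP": st.f_ap,
                     "f_AP_rel": st.f_ap / baseline if baseline > 0 else np.nan})
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    """Fitted per-state dissociation constants with bootstrap intervals."""

    affinities: PeptideAffinities
    rss: float
    n_points: int
    unidentifiable: list[str]
    ci_low: dict[str, float] | None = None
    ci_high: dict[str, float] | None = None


_PARAM_NAMES = {1: ["kd1_uM", "kd2p_uM"], 2: ["kd1_uM", "kd2_uM", "kd2p_uM"]}


def _affinities_from_vector(log10_kds: np.ndarray, variant: int) -> PeptideAffinities:
    kds = 10.0 ** np.asarray(log10_kds, dtype=float)
    if variant == 1:
        return PeptideAffinities(kd1_uM=kds[0], kd2_uM=1.0, kd2p_uM=kds[1],
                                 half_binds=False)
    return PeptideAffinities(kd1_uM=kds[0], kd2_uM=kds[1], kd2p_uM=kds[2])


def fit_affinities(data: pd.DataFrame, actin_uM: float, pevk_uM: float,
                   ca_params: CaBindingParams | None = None,
                   k_ap_uM: float = 0.5, variant: int = 2,
                   ca_depleted: bool = False,
                   n_bootstrap: int = 0, seed: int | None = None,
                   x0_uM: tuple[float, ...] | None = None) -> FitResult:
    """Least-squares fit of the per-state Kds to dose–response data.

    ``data`` needs columns s100_total_uM, f_AP, pCa; curves at different pCa
    are fitted jointly.  Optimisation runs on log₁₀ Kd with bounds
    [10⁻⁴, 10³] µM.  Parameters whose perturbation leaves the residual sum
    of squares essentially unchanged (flat profile) are flagged
    unidentifiable.  Optional residual-bootstrap confidence intervals
    (2.5/97.5 percentiles over ``n_bootstrap`` seeded replicates).
    """
    required = {"s100_total_uM", "f_AP", "pCa"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if variant not in _PARAM_NAMES:
        raise ValueError("variant must be 1 or 2")
    names = _PARAM_NAMES[variant]
    ca_params = ca_params or CaBindingParams()
    s_tot = data["s100_total_uM"].to_numpy(float)
    y = data["f_AP"].to_numpy(float)
    pcas = data["pCa"].to_numpy(float)
    if np.any(s_tot < 0):
        raise ValueError("concentrations must be non-negative")

    conditions = sorted({(st, pc) for st, pc in zip(s_tot, pcas)})

    def predict(log10_kds: np.ndarray) -> np.ndarray:
        aff = _affinities_from_vector(log10_kds, variant)
        f = {cond: solve_equilibrium(
                SystemTotals(cond[0], actin_uM, pevk_uM, cond[1], ca_depleted),
                ca_params, aff, k_ap_uM).f_ap
             for cond in conditions}     # replicates share one solve
        return np.array([f[(st, pc)] for st, pc in zip(s_tot, pcas)])

    def run_fit(target: np.ndarray, x0: np.ndarray) -> least_squares:
        return least_squares(lambda x: predict(x) - target, x0,
                             bounds=(-4.0, 3.0), method="trf", xtol=1e-12,
                             ftol=1e-12, gtol=1e-12)

    if x0_uM is None:
        x0 = np.full(len(names), -0.5)
    else:
        x0 = np.log10(np.asarray(x0_uM, dtype=float))
    res = run_fit(y, x0)
    rss = float(np.sum(res.fun ** 2))

    # identifiability: a parameter is flagged when shifting its log10 value
    # by a full decade barely moves the residuals
    unident = []
    scale = max(float(np.sum((y - y.mean()) ** 2)), 1e-12)
    for j, name in enumerate(names):
        x_pert = res.x.copy()
        x_pert[j] = min(x_pert[j] + 1.0, 3.0)
        d_rss = abs(float(np.sum((predict(x_pert) - y) ** 2)) - rss)
        if d_rss < 1e-6 * scale:
            unident.append(name)

    ci_low = ci_high = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        yhat = predict(res.x)
        resid = y - yhat
        draws = np.empty((n_bootstrap, len(names)))
        for t in range(n_bootstrap):
            y_star = yhat + rng.choice(resid, size=resid.size, replace=True)
            draws[t] = run_fit(y_star, res.x).x
        kd_draws = 10.0 ** draws
        ci_low = {n: float(np.percentile(kd_draws[:, j], 2.5))
                  for j, n in enumerate(names)}
        ci_high = {n: float(np.percentile(kd_draws[:, j], 97.5))
                   for j, n in enumerate(names)}

    return FitResult(_affinities_from_vector(res.x, variant), rss, y.size,
                     unident, ci_low, ci_high)


def predict_ptm_curves(affinities: PeptideAffinities,
                       s100_grid_uM: np.ndarray, actin_uM: float,
                       pevk_uM: float, pca_list: list[float],
                       scale_factor: float | None = None,
                       calibration: Calibration | None = None,
                       dg_mod: float = -12.9, dg_wt: float = -7.6,
                       ca_params: CaBindingParams | None = None,
                       k_ap_uM: float = 0.5,
                       ca_depleted: bool = False) -> pd.DataFrame:
    """Wild-type vs PTM dose–response curves at each pCa.

    The PTM curve uses Kd2 and Kd2′ multiplied by ``scale_factor`` (computed
    from the calibration and ΔG_mod/ΔG_WT when not given explicitly).
    Returns a frame (pCa, s100_total_uM, f_AP_wt, f_AP_ptm).
    """
    if scale_factor is None:
        scale_factor = ptm_scale_factor(dg_mod, dg_wt,
                                        calibration or calibrate_lambda())
    ptm_aff = affinities.scaled(scale_factor)
    frames = []
    for pca in pca_list:
        wt = dose_response(s100_grid_uM, actin_uM, pevk_uM, pca,
                           ca_params, affinities, k_ap_uM, ca_depleted)
        mod = dose_response(s100_grid_uM, actin_uM, pevk_uM, pca,
                            ca_params, ptm_aff, k_ap_uM, ca_depleted)
        frames.append(pd.DataFrame({
            "pCa": pca,
            "s100_total_uM": wt["s100_total_uM"],
            "f_AP_wt": wt["f_AP"],
            "f_AP_ptm": mod["f_AP"],
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["scale_factor"] = scale_factor
    return out
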