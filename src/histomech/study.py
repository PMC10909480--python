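"""Cohort studies over synthetic RVEs: parameter sweeps, benchmarking,
area-fraction correlations, tension-compression asymmetry and simple
group statistics.

The workflow mirrors how apparent tissue properties are explored when
the constituent properties themselves are uncertain: hold the geometry
(a cohort of RVEs) fixed, sweep the constituent material parameters
over their literature ranges, benchmark the resulting apparent
compressive moduli against the experimentally reported tissue range
(20 +/- 5 kPa for normal prostate), then correlate apparent stiffness
with constituent area fractions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constitutive import NeoHookeanParams, HGOParams, c10_from_youngs
from .homogenization import (
    mesh_from_labels,
    run_all_cases,
    apparent_moduli,
    ApparentModuli,
    NewtonDivergence,
)

# literature parameter ranges (kPa except k2, kappa dimensionless)
STROMA_C10_RANGE = (5.0, 30.0)
STROMA_K1_RANGE = (10.0, 300.0)
STROMA_K2 = 200.0
EPITHELIUM_E_RANGE = (1.0, 40.0)     # Young's moduli, converted to C10
LUMEN_C10_RANGE = (1.92, 192.0)
BENCHMARK_KPA = 20.0
BENCHMARK_HALFWIDTH_KPA = 5.0
DEFAULT_NU = 0.49

MODULI_COLS = ["E11t", "E11c", "E22t", "E22c", "G12t", "G12c"]


def grid5(lo: float, hi: float) -> np.ndarray:
    """Five evenly spaced levels including both bounds (midpoint = mean)."""
    return np.linspace(lo, hi, 5)


def default_epithelium_c10(nu: float = DEFAULT_NU) -> float:
    """Geometric mid-range of the converted epithelial C10 interval."""
    lo, hi = (c10_from_youngs(E, nu) for E in EPITHELIUM_E_RANGE)
    return float(np.sqrt(lo * hi))


def default_lumen_c10() -> float:
    """Geometric mid-range of the lumen C10 interval."""
    return float(np.sqrt(LUMEN_C10_RANGE[0] * LUMEN_C10_RANGE[1]))


def _materials(C10_S, k1_S, C10_E, C10_A, nu=DEFAULT_NU, kappa=0.0,
               k2=STROMA_K2):
    return {
        0: HGOParams(NeoHookeanParams.from_poisson(C10_S, nu), k1_S, k2,
                     kappa),
        1: NeoHookeanParams.from_poisson(C10_E, nu),
        2: NeoHookeanParams.from_poisson(C10_A, nu),
    }


def _solve_rve(model, materials, magnitude, **solver_kw):
    res = run_all_cases(model, materials, magnitude, **solver_kw)
    return apparent_moduli(res)


def stromal_parameter_sweep(rves: dict, C10_grid=None, k1_grid=None,
                            C10_E: float | None = None,
                            C10_A: float | None = None,
                            magnitude: float = 0.05, coarsen: int = 1,
                            **solver_kw) -> pd.DataFrame:
    """Full-factorial sweep of stromal C10 and k1 over a cohort of RVEs.

    ``rves`` maps an id to a PeriodicRVE (or LabelImage).  The default
    grids are five evenly spaced levels spanning the literature ranges
    (5-30 kPa for C10, 10-300 kPa for k1), whose midpoints are the
    benchmark values 17.5 and 155 kPa.  Epithelium and lumen are held
    at their geometric mid-range C10 unless given.  Failed solves are
    flagged rows, not dropped.
    """
    C10_grid = grid5(*STROMA_C10_RANGE) if C10_grid is None else \
        np.asarray(C10_grid, float)
    k1_grid = grid5(*STROMA_K1_RANGE) if k1_grid is None else \
        np.asarray(k1_grid, float)
    C10_E = default_epithelium_c10() if C10_E is None else C10_E
    C10_A = default_lumen_c10() if C10_A is None else C10_A

    rows = []
    for rve_id, rve in rves.items():
        model = mesh_from_labels(rve, coarsen=coarsen)
        for C10_S in C10_grid:
            for k1_S in k1_grid:
                row = {"rve": rve_id, "C10_S": float(C10_S),
                       "k1_S": float(k1_S), "C10_E": float(C10_E),
                       "C10_A": float(C10_A)}
                mats = _materials(C10_S, k1_S, C10_E, C10_A)
                try:
                    mod = _solve_rve(model, mats, magnitude, **solver_kw)
                    row.update(mod.as_dict())
                    row["failed"] = False
                except (NewtonDivergence, RuntimeError) as exc:
                    row.update({c: np.nan for c in MODULI_COLS})
                    row["failed"] = True
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def epithelium_lumen_sweep(rves: dict, C10_E_grid=None, C10_A_grid=None,
                           C10_S: float = 17.5, k1_S: float = 155.0,
                           magnitude: float = 0.05, coarsen: int = 1,
                           **solver_kw) -> pd.DataFrame:
    """Sweep epithelial and lumen C10 at the benchmarked stromal values.

    Stroma is fixed at the benchmark (C10 = 17.5 kPa, k1 = 155 kPa, the
    midpoints of the stromal sweep).  Epithelium levels default to five
    values spanning the converted 1-40 kPa Young's-modulus range; lumen
    levels span 1.92-192 kPa (log-spaced, two decades).
    """
    if C10_E_grid is None:
        C10_E_grid = np.array([c10_from_youngs(E) for E in
                               grid5(*EPITHELIUM_E_RANGE)])
    if C10_A_grid is None:
        C10_A_grid = np.geomspace(*LUMEN_C10_RANGE, 5)
    rows = []
    for rve_id, rve in rves.items():
        model = mesh_from_labels(rve, coarsen=coarsen)
        for C10_E in np.asarray(C10_E_grid, float):
            for C10_A in np.asarray(C10_A_grid, float):
                row = {"rve": rve_id, "C10_S": float(C10_S),
                       "k1_S": float(k1_S), "C10_E": float(C10_E),
                       "C10_A": float(C10_A)}
                mats = _materials(C10_S, k1_S, C10_E, C10_A)
                try:
                    mod = _solve_rve(model, mats, magnitude, **solver_kw)
                    row.update(mod.as_dict())
                    row["failed"] = False
                except (NewtonDivergence, RuntimeError) as exc:
                    row.update({c: np.nan for c in MODULI_COLS})
                    row["failed"] = True
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BenchmarkSelection:
    C10_S: float
    k1_S: float
    mean_compressive_kpa: float
    within_range: bool
    in_range_combinations: list


def benchmark_select(table: pd.DataFrame,
                     target_kpa: float = BENCHMARK_KPA,
                     halfwidth_kpa: float = BENCHMARK_HALFWIDTH_KPA
                     ) -> BenchmarkSelection:
    """Pick the stromal (C10, k1) whose mean compressive modulus best
    matches the literature target.

    The aggregate is the mean of E11c and E22c over all RVEs for each
    parameter combination; ties break toward smaller C10, then smaller
    k1.  If nothing lies inside [target +/- halfwidth] the closest
    combination is returned flagged out-of-range.
    """
    ok = table[~table["failed"]] if "failed" in table else table
    if ok.empty:
        raise ValueError("no successful rows to benchmark")
    agg = (ok.groupby(["C10_S", "k1_S"])[["E11c", "E22c"]]
             .mean().mean(axis=1).rename("mean_compressive").reset_index())
    agg["dist"] = (agg["mean_compressive"] - target_kpa).abs()
    agg = agg.sort_values(["dist", "C10_S", "k1_S"],
                          kind="mergesort").reset_index(drop=True)
    best = agg.iloc[0]
    in_range = agg[agg["dist"] <= halfwidth_kpa]
    return BenchmarkSelection(
        C10_S=float(best["C10_S"]),
        k1_S=float(best["k1_S"]),
        mean_compressive_kpa=float(best["mean_compressive"]),
        within_range=bool(best["dist"] <= halfwidth_kpa),
        in_range_combinations=[(float(r["C10_S"]), float(r["k1_S"]))
                               for _, r in in_range.iterrows()],
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def correlate_fractions(moduli_by_rve: dict, fractions_by_rve: dict
                        ) -> dict:
    """OLS of the mean apparent modulus on each constituent area fraction.

    The response per RVE is the mean of E11 and E22 (averaged over
    tension and compression when both are present in the ApparentModuli
    record).  Returns {'stroma': RegressionResult, 'epithelium': ...,
    'lumen': ...}.  A constant response is defined to have R^2 = 0.
    """
    ids = sorted(moduli_by_rve)
    if len(ids) < 3:
        raise ValueError("need at least 3 RVEs to regress")
    if set(ids) != set(fractions_by_rve):
        raise ValueError("moduli and fractions must cover the same RVEs")
    y = []
    for i in ids:
        m = moduli_by_rve[i]
        if isinstance(m, ApparentModuli):
            y.append(np.mean([m.E11t, m.E11c, m.E22t, m.E22c]))
        else:
            y.append(float(np.mean(m)))
    y = np.asarray(y)
    out = {}
    for ci, name in enumerate(("stroma", "epithelium", "lumen")):
        x = np.asarray([fractions_by_rve[i][ci] for i in ids], float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            out[name] = RegressionResult(0.0, float(y.mean()), 0.0)
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean())**2))
        out[name] = RegressionResult(float(slope), float(intercept),
                                     1.0 - ss_res / ss_tot)
    return out


def asymmetry_index(m: ApparentModuli) -> tuple:
    """Per-direction relative tension excess (Et - Ec) / Ec."""
    if m.E11c <= 0 or m.E22c <= 0:
        raise ValueError("compressive moduli must be positive")
    return ((m.E11t - m.E11c) / m.E11c, (m.E22t - m.E22c) / m.E22c)


def welch_t_test(group_a, group_b):
    """Two-sided Welch t-test with significance stars.

    Stars follow the usual thresholds: NS (p >= .05), * (p < .05),
    ** (p < .01), *** (p < .001).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.array_equal(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if p < 0.001:
        star = "***"
    elif p < 0.01:
        star = "**"
    elif p < 0.05:
        star = "*"
    else:
        star = "NS"
    return float(t), float(p), star


def write_report(tables: dict, scalars: dict, out_dir) -> None:
    """CSV per table, one JSON for scalars/metadata; deterministic order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in sorted(tables):
        df = tables[name]
        df.to_csv(out_dir / f"{name}.csv", index=False)
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    (out_dir / "report.json").write_text(
        json.dumps(scalars, indent=2, sort_keys=True, default=_default))
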