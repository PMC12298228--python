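"""Virtual between-subject variability and gated group comparisons.

Virtual subjects are drawn by treating the optimized parameter values as
medians and drawing every model parameter independently from a normal
distribution with SD equal to a fixed fraction of the median (default 10%),
truncated to strictly positive values by resampling. By default each
genotype group draws its own global-parameter values ("independent" mode);
a "matched" mode reuses one set of global draws across genotypes so groups
differ only in their genotype-specific constants.

Group comparison follows standard gated practice: Shapiro-Wilk normality
and Levene equal-variance checks at p < 0.05 choose between parametric
(one-way ANOVA, pairwise t-test) and nonparametric (Kruskal-Wallis,
Mann-Whitney) tests, with a Bonferroni pairwise cutoff of
0.05 / number-of-groups (0.0167 for three genotypes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InvalidParameterError
from .model import simulate
from .params import DoseRegimen, ModelParameters
from .pk import DEFAULT_AUC_HORIZON, pk_summary

__all__ = [
    "PopulationSpec",
    "PopulationSample",
    "draw_parameters",
    "sample_population",
    "compare_groups",
]

_GENOTYPE_LOCAL = ("k_m", "k_ent_int")


@dataclass(frozen=True)
class PopulationSpec:
    """Design of a virtual population draw."""

    genotypes: tuple[str, ...]
    n_per_genotype: int = 100
    sd_fraction: float = 0.10
    seed: int = 0
    dose_mg: float = 50.0
    mode: str = "independent"  # or "matched"

    def __post_init__(self) -> None:
        if self.n_per_genotype < 2:
            raise InvalidParameterError("n_per_genotype must be >= 2")
        if not (0 <= self.sd_fraction < 1):
            raise InvalidParameterError("sd_fraction must be in [0, 1)")
        if self.mode not in {"independent", "matched"}:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if not self.genotypes:
            raise InvalidParameterError("at least one genotype required")


def _draw_column(rng: np.random.Generator, median: float, sd: float, n: int) -> np.ndarray:
    """Normal(median, sd) truncated to > 0 by resampling (keeps the shape)."""
    if sd == 0 or median == 0:
        return np.full(n, median)
    out = rng.normal(median, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(median, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def draw_parameters(
    spec: PopulationSpec,
    base_params_by_genotype: Mapping[str, ModelParameters],
) -> pd.DataFrame:
    """Draw per-subject parameter sets; long format draw_id/genotype/parameter/value."""
    for g in spec.genotypes:
        if g not in base_params_by_genotype:
            raise InvalidParameterError(f"no base parameters for genotype {g!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_genotype
    records = []
    shared_draws: dict[str, np.ndarray] = {}
    for g in spec.genotypes:
        base = base_params_by_genotype[g].to_dict()
        for name, median in base.items():
            if spec.mode == "matched" and name not in _GENOTYPE_LOCAL:
                if name not in shared_draws:
                    shared_draws[name] = _draw_column(
                        rng, median, spec.sd_fraction * median, n
                    )
                col = shared_draws[name]
            else:
                col = _draw_column(rng, median, spec.sd_fraction * median, n)
            for i, v in enumerate(col):
                records.append(
                    {"draw_id": i, "genotype": g, "parameter": name, "value": float(v)}
                )
    return pd.DataFrame.from_records(records)


@dataclass
class PopulationSample:
    """Drawn parameter sets with per-draw PK summaries."""

    spec: PopulationSpec
    parameters: pd.DataFrame
    pk: pd.DataFrame

    def pk_by_genotype(self, metric: str) -> dict[str, np.ndarray]:
        return {
            g: grp[metric].to_numpy() for g, grp in self.pk.groupby("genotype", sort=False)
        }

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.parameters.to_csv(directory / "population_parameters.csv", index=False)
        self.pk.to_csv(directory / "population_pk.csv", index=False)


def sample_population(
    spec: PopulationSpec,
    base_params_by_genotype: Mapping[str, ModelParameters],
    horizon: float = DEFAULT_AUC_HORIZON,
    output_step: float = 0.01,
    **solver_kwargs,
) -> PopulationSample:
    """Draw virtual subjects and compute their single-dose PK metrics."""
    solver_kwargs.setdefault("rtol", 1e-8)
    solver_kwargs.setdefault("atol", 1e-10)
    draws = draw_parameters(spec, base_params_by_genotype)
    dose = DoseRegimen(dose_mg=spec.dose_mg)
    wide = draws.pivot_table(
        index=["genotype", "draw_id"], columns="parameter", values="value", sort=False
    )
    rows = []
    for (g, i), row in wide.iterrows():
        params = ModelParameters.from_dict(row.to_dict())
        series = simulate(
            params, dose, t_end=horizon, output_step=output_step,
            genotype_label=g, **solver_kwargs,
        )
        summ = pk_summary(series, dose, horizon=horizon, half_life=False)
        rows.append(
            {
                "draw_id": i,
                "genotype": g,
                "Cmax_losartan": summ.cmax_losartan,
                "tmax_losartan": summ.tmax_losartan,
                "AUC0inf_losartan": summ.auc0inf_losartan,
                "CL_F": summ.cl_over_f,
                "Cmax_E3174": summ.cmax_E3174,
                "tmax_E3174": summ.tmax_E3174,
                "AUC0inf_E3174": summ.auc0inf_E3174,
            }
        )
    return PopulationSample(spec=spec, parameters=draws, pk=pd.DataFrame(rows))


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # degenerate sample; treat as non-normal
        return False
    try:
        return stats.shapiro(x).pvalue > alpha
    except Exception:
        return False


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    metric: str | None = None,
) -> dict:
    """Gated omnibus + pairwise comparison across genotype groups.

    Returns a JSON-serializable report: the gate outcomes, the omnibus test
    (one-way ANOVA if every group passes normality and the variances are
    equal, Kruskal-Wallis otherwise), and each pairwise comparison with its
    test, statistic, p-value and decision at the Bonferroni cutoff
    alpha / number-of-groups.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise AnalysisError("need at least two groups")
    for name, x in groups.items():
        if len(x) < 3:
            raise AnalysisError(f"group {name!r} has fewer than 3 values")

    names = list(groups)
    arrays = [groups[n] for n in names]
    normal = {n: _is_normal(groups[n], alpha) for n in names}
    degenerate = all(np.ptp(x) == 0 for x in arrays) and len(
        {x[0] for x in arrays}
    ) == 1
    try:
        levene_p = float(stats.levene(*arrays).pvalue)
    except Exception:
        levene_p = 1.0
    equal_var = levene_p > alpha
    parametric = all(normal.values()) and equal_var

    if degenerate:
        omnibus = {"test": "none (all values identical)", "statistic": 0.0, "p": 1.0}
    elif parametric:
        st = stats.f_oneway(*arrays)
        omnibus = {"test": "one-way ANOVA", "statistic": float(st.statistic), "p": float(st.pvalue)}
    else:
        st = stats.kruskal(*arrays)
        omnibus = {
            "test": "Kruskal-Wallis",
            "statistic": float(st.statistic),
            "p": float(st.pvalue),
        }

    cutoff = alpha / len(names)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            if np.ptp(np.concatenate([a, b])) == 0:
                test, statistic, p = "none (identical values)", 0.0, 1.0
            elif parametric:
                st = stats.ttest_ind(a, b, equal_var=True)
                test, statistic, p = "t-test", float(st.statistic), float(st.pvalue)
            else:
                st = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
                test, statistic, p = (
                    "Mann-Whitney (asymptotic, continuity-corrected)",
                    float(st.statistic),
                    float(st.pvalue),
                )
            pairwise.append(
                {
                    "groups": [names[i], names[j]],
                    "test": test,
                    "statistic": statistic,
                    "p": p,
                    "cutoff": cutoff,
                    "significant": bool(p < cutoff),
                }
            )
    return {
        "metric": metric,
        "alpha": alpha,
        "normality_p_gate": alpha,
        "normal_by_group": normal,
        "equal_variance_p": levene_p,
        "parametric": parametric,
        "omnibus": omnibus,
        "pairwise_cutoff": cutoff,
        "pairwise": pairwise,
    }
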