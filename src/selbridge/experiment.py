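"""Four-case parameter-recovery study and ensemble summaries.

For each observation case (I–IV) an ensemble of endpoint-conditioned
trajectories is simulated at a known selection coefficient, both likelihoods
are maximized per trajectory, and the ensemble of maximizers is summarized
by its mode (Gaussian KDE on ``log s``, Silverman bandwidth) and empirical
95% confidence interval.  Defaults reproduce the study conditions of the
recovery experiment: ``N = 54`` alleles, ``N_B(0) = 27``, true ``s = 2``,
``T = 500`` generations (Moran) or ``T = 100`` (Wright–Fisher),
intermediate endpoint ``k = 40`` for cases I/III, fixation ``k = N`` for
cases II/IV (``k = N - 1``, near fixation, in the Wright–Fisher variant),
100 trajectories per case.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .conditioning import InfeasibleBridgeError
from .likelihood import (
    ConditionalLikelihood,
    EstimationError,
    UnconditionalLikelihood,
    maximize,
)
from .models import Family, ModelSpec, _as_family
from .simulate import CASES, CaseSpec, encode_transitions, simulate_conditioned

logger = logging.getLogger(__name__)

CASE_INDEX = {c: n for n, c in enumerate(CASES, start=1)}
KINDS = ("conditional", "unconditional")


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one recovery experiment (one model family)."""

    family: Family
    N: int = 54
    s_true: float = 2.0
    N_B0: int = 27
    T: int = 500
    k_intermediate: int = 40
    near_fixation: bool = False  # use k = N - 1 instead of N in cases II/IV
    n_traj: int = 100
    seed: int = 0
    s_min: float = 0.05
    s_max: float = 20.0
    n_grid: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", _as_family(self.family))

    @classmethod
    def moran_defaults(cls, **overrides) -> "ExperimentConfig":
        """Moran study: T = 500, k = N for fixation cases."""
        base = dict(family=Family.MORAN, T=500, near_fixation=False)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def wright_fisher_defaults(cls, **overrides) -> "ExperimentConfig":
        """Wright–Fisher study: T = 100, k = N - 1 (near fixation) for II/IV."""
        base = dict(family=Family.WRIGHT_FISHER, T=100, near_fixation=True)
        base.update(overrides)
        return cls(**base)

    def k_for_case(self, case: str) -> int:
        if case in ("I", "III"):
            return self.k_intermediate
        return self.N - 1 if self.near_fixation else self.N

    def case_spec(self, case: str) -> CaseSpec:
        return CaseSpec(case=case, N_B0=self.N_B0, T=self.T, k=self.k_for_case(case))

    def replace(self, **overrides) -> "ExperimentConfig":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class EnsembleSummary:
    """Mode and 95% CI of the MLE distribution for one case x kind."""

    case: str
    kind: str
    mode: float
    ci_low: float
    ci_high: float
    n_total: int
    n_used: int
    n_boundary: int
    n_failed: int
    estimates: np.ndarray = field(repr=False)


def ensemble_mode_ci(estimates) -> tuple[float, float, float]:
    """Mode (KDE on ``log s``, Silverman bandwidth) and empirical 95% CI."""
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est) & (est > 0)]
    if est.size == 0:
        raise ValueError("no finite positive estimates to summarize")
    ci_low, ci_high = np.percentile(est, [2.5, 97.5])
    logs = np.log(est)
    if est.size == 1 or np.ptp(logs) < 1e-12:
        return float(est[0]), float(ci_low), float(ci_high)
    kde = stats.gaussian_kde(logs, bw_method="silverman")
    pad = 3.0 * logs.std(ddof=1) * est.size ** (-0.2) + 1e-6
    grid = np.linspace(logs.min() - pad, logs.max() + pad, 1024)
    mode = float(np.exp(grid[np.argmax(kde(grid))]))
    return mode, float(ci_low), float(ci_high)


@dataclass(frozen=True)
class CaseResult:
    """Per-trajectory fits and per-kind summaries for one case."""

    case: str
    table: pd.DataFrame
    summaries: dict


def run_case(
    config: ExperimentConfig,
    case: str,
    kinds: tuple = KINDS,
    progress: bool = False,
) -> CaseResult:
    """Simulate, fit and summarize one case of the recovery study.

    Per-trajectory failures (flat likelihoods, infeasible bridges) are
    logged and counted, never abort the ensemble.  Fully reproducible from
    ``config.seed``: trajectory ``r`` of case ``c`` uses the RNG stream
    seeded with ``[seed, case_index(c), r]``.
    """
    case_spec = config.case_spec(case)
    model = ModelSpec(config.family, config.N, config.s_true)
    cond = case_spec.conditioning()

    evaluators = {}
    if "conditional" in kinds or "ratio" in kinds:
        evaluators["conditional"] = ConditionalLikelihood(config.family, config.N, cond)
    if "unconditional" in kinds or "ratio" in kinds:
        evaluators["unconditional"] = UnconditionalLikelihood(config.family, config.N)

    rows = []
    iterator = range(config.n_traj)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=f"case {case}")
        except ImportError:
            pass
    for r in iterator:
        rng = np.random.default_rng([config.seed, CASE_INDEX[case], r])
        traj = simulate_conditioned(model, case_spec, seed=rng)
        data = encode_transitions(traj)
        for kind in kinds:
            if kind == "ratio":
                ev_c, ev_u = evaluators["conditional"], evaluators["unconditional"]
                fun = lambda s: ev_c.loglik(data, s) - ev_u.loglik(data, s)  # noqa: E731
            else:
                ev = evaluators[kind]
                fun = lambda s: ev.loglik(data, s)  # noqa: E731
            record = dict(trajectory_id=r, case=case, kind=kind, s_hat=np.nan,
                          loglik=np.nan, boundary_flag=False,
                          multimodal_flag=False, failed=False)
            try:
                res = maximize(fun, s_min=config.s_min, s_max=config.s_max,
                               n_grid=config.n_grid, kind=kind)
                record.update(s_hat=res.s_hat, loglik=res.loglik,
                              boundary_flag=res.boundary,
                              multimodal_flag=res.multimodal)
                logger.info("case %s traj %d %s: s_hat=%.4g loglik=%.4g%s%s",
                            case, r, kind, res.s_hat, res.loglik,
                            " [boundary]" if res.boundary else "",
                            " [multimodal]" if res.multimodal else "")
            except (EstimationError, InfeasibleBridgeError) as exc:
                record["failed"] = True
                logger.warning("case %s traj %d %s: fit failed (%s)", case, r, kind, exc)
            rows.append(record)
    table = pd.DataFrame(rows)

    summaries = {}
    for kind in kinds:
        sub = table[table["kind"] == kind]
        ok = sub[~sub["failed"] & ~sub["boundary_flag"]]
        estimates = ok["s_hat"].to_numpy()
        if estimates.size:
            mode, lo, hi = ensemble_mode_ci(estimates)
        else:
            mode = lo = hi = np.nan
        summaries[kind] = EnsembleSummary(
            case=case, kind=kind, mode=mode, ci_low=lo, ci_high=hi,
            n_total=len(sub), n_used=len(ok),
            n_boundary=int(sub["boundary_flag"].sum()),
            n_failed=int(sub["failed"].sum()), estimates=estimates,
        )
    return CaseResult(case=case, table=table, summaries=summaries)


def summary_frame(results: "list[CaseResult]") -> pd.DataFrame:
    rows = []
    for res in results:
        for kind, summ in res.summaries.items():
            rows.append(dict(case=summ.case, kind=kind, mode=summ.mode,
                             ci_low=summ.ci_low, ci_high=summ.ci_high,
                             n_used=summ.n_used, n_boundary=summ.n_boundary,
                             n_failed=summ.n_failed))
    return pd.DataFrame(rows)


def reproduce_figure(
    which: str,
    outdir=None,
    cases: tuple = CASES,
    plot: bool = True,
    progress: bool = False,
    **overrides,
) -> pd.DataFrame:
    """Run the full recovery study for one model family.

    ``which`` selects the family: ``"fig2"`` is the Moran study (T = 500,
    fixation cases at k = N), ``"fig3"`` the Wright–Fisher study (T = 100,
    near-fixation cases at k = N - 1).  Writes per-trajectory and summary
    TSV tables (and a mode/CI plot) to ``outdir`` when given; returns the
    summary table.
    """
    if which == "fig2":
        config = ExperimentConfig.moran_defaults(**overrides)
    elif which == "fig3":
        config = ExperimentConfig.wright_fisher_defaults(**overrides)
    else:
        raise ValueError("which must be 'fig2' or 'fig3'")
    results = [run_case(config, case, progress=progress) for case in cases]
    summary = summary_frame(results)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fits = pd.concat([r.table for r in results], ignore_index=True)
        fits.to_csv(out / f"{which}_fits.tsv", sep="\t", index=False)
        summary.to_csv(out / f"{which}_summary.tsv", sep="\t", index=False)
        if plot:
            _plot_summary(summary, config, out / f"{which}_modes.png")
    return summary


def _plot_summary(summary: pd.DataFrame, config: ExperimentConfig, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    offsets = {"conditional": -0.12, "unconditional": 0.12}
    colors = {"conditional": "tab:red", "unconditional": "tab:gray"}
    cases = list(dict.fromkeys(summary["case"]))
    for kind in offsets:
        sub = summary[summary["kind"] == kind]
        if sub.empty:
            continue
        x = np.array([cases.index(c) for c in sub["case"]]) + offsets[kind]
        y = sub["mode"].to_numpy()
        yerr = np.vstack([y - sub["ci_low"], sub["ci_high"] - y])
        ax.errorbar(x, y, yerr=np.clip(yerr, 0, None), fmt="s",
                    color=colors[kind], label=kind, capsize=4)
    ax.axhline(config.s_true, ls="--", color="k", lw=1)
    ax.set_xticks(range(len(cases)), [f"case {c}" for c in cases])
    ax.set_ylabel("estimated selection coefficient $\\hat{s}$")
    ax.set_yscale("log")
    ax.legend()
    ax.set_title(f"{config.family.value} (mode and 95% CI, n={config.n_traj})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
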