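"""Replicate-level simulation harness: type-I error, power, bias, SE.

Runs a scenario (or a grid of scenarios) replicate by replicate, fits the
requested estimators to each simulated cohort, and aggregates rejection
rates, mean estimates and both empirical and mean model-based standard
errors.  The individual-level estimators (PLDMR, PLDMR_t, PLDMR_a, LDMR)
see the full sample; the summary-statistic baselines (MR-Egger, IVW) are
served a two-sample design by permuting the individuals once per replicate
and computing the exposure associations from the first half and the outcome
associations from the second half.

Per-method failures (non-convergence, singular Gram) are caught, counted in
``n_failed``, and excluded from that method's aggregates — never silently
dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import estimators as est
from .model_core import GenotypeMatrix, PhenotypePair, VarianceComponents, joint_coefs, marginal_coefs
from .simulate import ScenarioConfig, simulate_dataset

__all__ = [
    "METHODS",
    "ExperimentResult",
    "run_replicate",
    "run_scenario",
    "grid",
    "scenario_hash",
    "plot_rejection_rates",
]

logger = logging.getLogger(__name__)

#: Canonical method labels accepted by the harness.
METHODS = ("PLDMR", "PLDMR_t", "PLDMR_a", "LDMR", "MR-Egger", "IVW")

#: Aliases accepted on the command line.
METHOD_ALIASES = {
    "pldmr": "PLDMR",
    "pldmr_t": "PLDMR_t",
    "pldmr_a": "PLDMR_a",
    "ldmr": "LDMR",
    "egger": "MR-Egger",
    "mr-egger": "MR-Egger",
    "ivw": "IVW",
}


def canonical_methods(methods) -> list[str]:
    out = []
    for name in methods:
        key = METHOD_ALIASES.get(str(name).lower(), name)
        if key not in METHODS:
            raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
        out.append(key)
    return out


@dataclass
class ExperimentResult:
    """Aggregated Monte-Carlo summaries of one scenario."""

    scenario: ScenarioConfig
    per_method: list[dict] = field(default_factory=list)
    wall_reps: int = 0


def _replicate_rng(cfg: ScenarioConfig, rep_index: int) -> np.random.Generator:
    """One independent, reproducible stream per (scenario seed, replicate)."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, rep_index]))


def run_replicate(
    cfg: ScenarioConfig,
    rep_index: int,
    methods=METHODS,
    mafs=None,
    gammas=None,
) -> dict[str, est.MRFit | Exception]:
    """Simulate one cohort and fit every requested estimator to it.

    Returns a dict mapping method label to an :class:`~pldmr.estimators.MRFit`
    or, for a failed fit, the exception raised (the replicate continues).
    """
    methods = canonical_methods(methods)
    rng = _replicate_rng(cfg, rep_index)
    ds = simulate_dataset(cfg, rng, mafs=mafs, gammas=gammas)
    G = ds.genotypes.center()
    P = ds.phenotypes.center()
    out: dict[str, est.MRFit | Exception] = {}

    jc = None
    needs_joint = any(m in methods for m in ("PLDMR", "PLDMR_t", "PLDMR_a", "LDMR"))
    if needs_joint:
        try:
            jc = joint_coefs(G, P)
        except Exception as exc:  # Gram failure poisons all joint methods
            for m in methods:
                if m in ("PLDMR", "PLDMR_t", "PLDMR_a", "LDMR"):
                    out[m] = exc

    vc_true = VarianceComponents(
        mu_alpha=cfg.mu_alpha,
        sigma_alpha2=cfg.sigma_alpha**2,
        sigma_y2=cfg.sigma_y**2,
    )
    fitters = {
        "PLDMR": lambda: est.fit_pldmr(G, P, jc=jc),
        "PLDMR_t": lambda: est.fit_pldmr_t(G, P, vc_true, jc=jc),
        "PLDMR_a": lambda: est.fit_pldmr_a(jc),
        "LDMR": lambda: est.fit_ldmr(G, P, jc=jc),
    }
    for m in methods:
        if m in fitters and m not in out:
            try:
                out[m] = fitters[m]()
            except Exception as exc:
                out[m] = exc

    if "MR-Egger" in methods or "IVW" in methods:
        try:
            mc = _split_half_marginals(ds, rng)
            if "MR-Egger" in methods:
                out["MR-Egger"] = est.fit_mr_egger(mc)
            if "IVW" in methods:
                out["IVW"] = est.fit_ivw(mc)
        except Exception as exc:
            for m in ("MR-Egger", "IVW"):
                if m in methods and m not in out:
                    out[m] = exc
    return out


def _split_half_marginals(ds, rng: np.random.Generator):
    """Two-sample summary statistics by a seeded half split.

    After a random permutation, the first floor(n/2) individuals yield the
    per-variant exposure slopes and the remainder the outcome slopes and
    their SEs, mimicking the two independent GWAS samples that
    summary-statistic MR methods assume.
    """
    n = ds.genotypes.n
    perm = rng.permutation(n)
    half = n // 2
    a_idx, b_idx = perm[:half], perm[half:]
    vals = ds.genotypes.values
    Ga = GenotypeMatrix(vals[a_idx], centered=False)
    Gb = GenotypeMatrix(vals[b_idx], centered=False)
    x = ds.phenotypes.exposure
    y = ds.phenotypes.outcome
    mc_a = marginal_coefs(Ga, PhenotypePair(x[a_idx], x[a_idx]))
    mc_b = marginal_coefs(Gb, PhenotypePair(y[b_idx], y[b_idx]))
    from .model_core import MarginalCoefs

    return MarginalCoefs(
        gamma_tilde=mc_a.gamma_tilde,
        Gamma_tilde=mc_b.Gamma_tilde,
        se_Gamma_tilde=mc_b.se_Gamma_tilde,
    )


def run_scenario(cfg: ScenarioConfig, methods=METHODS) -> ExperimentResult:
    """Run ``cfg.n_reps`` replicates and aggregate per-method summaries.

    Rejection is a two-sided test of H0: beta = 0 at ``cfg.alpha_level``.
    The Monte-Carlo SE of the rejection rate is sqrt(p(1-p)/n_used).
    """
    methods = canonical_methods(methods)
    t0 = time.monotonic()
    mafs = gammas = None
    if not cfg.redraw_per_replicate:
        rng0 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**30]))
        mafs = rng0.uniform(cfg.maf_low, cfg.maf_high, size=cfg.m)
        gammas = rng0.uniform(cfg.gamma_low, cfg.gamma_high, size=cfg.m)

    records: dict[str, list[est.MRFit]] = {m: [] for m in methods}
    failures: dict[str, int] = {m: 0 for m in methods}
    for rep in range(cfg.n_reps):
        fits = run_replicate(cfg, rep, methods, mafs=mafs, gammas=gammas)
        for m in methods:
            res = fits.get(m)
            if isinstance(res, est.MRFit):
                records[m].append(res)
            else:
                failures[m] += 1
                logger.debug("rep %d method %s failed: %s", rep, m, res)

    per_method = []
    for m in methods:
        fits = records[m]
        n_used = len(fits)
        if n_used:
            betas = np.array([f.beta_hat for f in fits])
            ses = np.array([f.se_beta for f in fits])
            pvals = np.array([f.p_value for f in fits])
            rate = float(np.mean(pvals < cfg.alpha_level))
            per_method.append({
                "method": m,
                "rejection_rate": rate,
                "rejection_mc_se": float(np.sqrt(rate * (1 - rate) / n_used)),
                "mean_beta_hat": float(betas.mean()),
                "empirical_se": float(betas.std(ddof=1)) if n_used > 1 else float("nan"),
                "mean_model_se": float(ses.mean()),
                "n_used": n_used,
                "n_failed": failures[m],
            })
        else:
            per_method.append({
                "method": m,
                "rejection_rate": float("nan"),
                "rejection_mc_se": float("nan"),
                "mean_beta_hat": float("nan"),
                "empirical_se": float("nan"),
                "mean_model_se": float("nan"),
                "n_used": 0,
                "n_failed": failures[m],
            })
    logger.info(
        "scenario %s: %d reps in %.1fs", scenario_hash(cfg), cfg.n_reps,
        time.monotonic() - t0,
    )
    return ExperimentResult(scenario=cfg, per_method=per_method, wall_reps=cfg.n_reps)


def scenario_hash(cfg: ScenarioConfig) -> str:
    """Stable 12-hex digest of the canonicalized scenario config."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


_GRID_COLUMNS = [
    "scenario_hash", "n", "m", "rho_g", "mu_alpha", "sigma_alpha", "beta",
    "sigma_x", "sigma_y", "rho", "n_reps", "seed", "alpha_level", "method",
    "rejection_rate", "rejection_mc_se", "mean_beta_hat", "empirical_se",
    "mean_model_se", "n_used", "n_failed",
]


def grid(scenarios, methods=METHODS, out_path=None) -> "pandas.DataFrame":
    """Run a list of scenarios; one tidy row per (scenario, method).

    When ``out_path`` is given the table is written as TSV after each
    scenario and completed scenario hashes already present in the file are
    skipped on re-run, making long grids resumable.
    """
    import pandas as pd

    if not scenarios:
        raise ValueError("scenario list is empty")
    methods = canonical_methods(methods)
    done: set[str] = set()
    rows: list[dict] = []
    if out_path is not None:
        try:
            prev = pd.read_csv(out_path, sep="\t")
            rows = prev.to_dict("records")
            done = set(prev["scenario_hash"].astype(str))
        except (FileNotFoundError, pd.errors.EmptyDataError):
            pass
    for cfg in scenarios:
        h = scenario_hash(cfg)
        if h in done:
            logger.info("scenario %s already complete; skipping", h)
            continue
        result = run_scenario(cfg, methods)
        for rec in result.per_method:
            row = {
                "scenario_hash": h,
                "n": cfg.n, "m": cfg.m, "rho_g": cfg.rho_g,
                "mu_alpha": cfg.mu_alpha, "sigma_alpha": cfg.sigma_alpha,
                "beta": cfg.beta, "sigma_x": cfg.sigma_x, "sigma_y": cfg.sigma_y,
                "rho": cfg.rho, "n_reps": cfg.n_reps, "seed": cfg.seed,
                "alpha_level": cfg.alpha_level,
            }
            row.update(rec)
            rows.append(row)
        if out_path is not None:
            pd.DataFrame(rows, columns=_GRID_COLUMNS).to_csv(
                out_path, sep="\t", index=False, float_format="%.17g",
            )
    return pd.DataFrame(rows, columns=_GRID_COLUMNS)


def plot_rejection_rates(table, out_path, alpha_level: float = 0.05):
    """Bar plot of rejection rates, one panel per (mu_alpha, rho_g) cell."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mus = sorted(table["mu_alpha"].unique())
    rgs = sorted(table["rho_g"].unique())
    fig, axes = plt.subplots(
        len(rgs), len(mus), figsize=(4 * len(mus), 3 * len(rgs)),
        squeeze=False, sharey=True,
    )
    for i, rg in enumerate(rgs):
        for j, mu in enumerate(mus):
            ax = axes[i][j]
            sub = table[(table["mu_alpha"] == mu) & (table["rho_g"] == rg)]
            for method, g in sub.groupby("method"):
                g = g.sort_values("n")
                ax.bar(
                    [f"{int(n)}\n{method}" for n in g["n"]],
                    g["rejection_rate"], label=method,
                )
            ax.axhline(alpha_level, color="red", linestyle="--", linewidth=1)
            ax.set_title(f"mu_alpha={mu}, rho_g={rg}", fontsize=9)
            ax.tick_params(axis="x", labelsize=6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
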