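"""Monte-Carlo projection with beta-sampled vital rates.

Two variance components drive the simulations, mirroring the distinction
between parameter uncertainty and environmental variability:

* *sampling* variance — drawn once per trajectory, from the published
  confidence intervals of adult survival and transient probability
  (CI width / 3.92 taken as a standard error);
* *process* variance — drawn every year, as a configurable coefficient of
  variation (default 0.05) applied to every survival and proportion, and a
  truncated-normal draw of seasonal fecundity whose CV propagates the
  published clutch-size and clutch-frequency standard deviations.

Yearly environmental deviates are shared between the Costa Rica and México
blocks (same environment, Gaussian-copula mapping into each block's beta
marginal); sampling draws are independent between blocks.  The default
initial vector follows the observed state of the population: 176 annual
breeders split by nesting shares, plus the hatchlings they produce, with
the unobserved juvenile and at-sea pools empty.

The reported deterministic growth rate is the mean annual rate of the
100-year projection at exact mean rates; the stochastic rate lambda_s is
``exp`` of the grand mean of per-trajectory mean annual log growth of total
females.  Quasi-extinction is declared when the subadult + adult female
pool (the observable segment of the population) falls below a threshold of
one female.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .matrix_model import (
    BLOCKS,
    LATE_STAGES,
    ProjectionMatrix,
    assemble_block,
    build_projection_matrix,
    mixture_ssd,
)
from .vital_rates import SubpopulationSet, VitalRates

__all__ = [
    "VarianceModel",
    "StochasticSpec",
    "TrajectoryEnsemble",
    "ProjectionResult",
    "sample_vital_rates",
    "initial_vector",
    "project_ensemble",
    "deterministic_projection",
    "stochastic_lambda",
    "extinction_metrics",
    "project_result",
]

DEFAULT_BREEDERS = 176.0
_Z_KEYS = ("s1", "s2", "s3", "b1", "b2", "b3", "b4", "transient", "f", "stw", "fem")


def _beta_ab(mean, var):
    k = mean * (1.0 - mean) / var - 1.0
    if np.any(k <= 0):
        raise ValueError("invalid beta parameterization (variance too large)")
    return mean * k, (1.0 - mean) * k


def beta_from_normal(z, mean, sd):
    """Gaussian-copula beta draw; exact mean when the variance is zero."""
    mean = np.asarray(mean, dtype=float)
    z = np.asarray(z, dtype=float)
    out = np.broadcast_to(mean, np.broadcast_shapes(z.shape, mean.shape)).copy()
    var = np.broadcast_to(np.asarray(sd, dtype=float) ** 2, out.shape).copy()
    feasible = np.minimum(var, 0.999 * out * (1.0 - out))
    mask = (feasible > 0) & (out > 0) & (out < 1)
    if np.any(mask):
        a, b = _beta_ab(out[mask], feasible[mask])
        zz = np.broadcast_to(z, out.shape)[mask]
        out[mask] = stats.beta.ppf(stats.norm.cdf(zz), a, b)
    return out


def truncnorm_fecundity(z, mean, cv):
    """Zero-truncated normal draw of eggs/female/season, mean-corrected.

    Truncation at zero inflates the raw truncated-normal mean, so the
    location is rescaled to keep the draw's expectation at ``mean``.
    """
    if cv <= 0:
        return np.broadcast_to(np.asarray(mean, dtype=float), np.shape(z)).copy()
    alpha = -1.0 / cv
    inflation = 1.0 + cv * stats.norm.pdf(alpha) / (1.0 - stats.norm.cdf(alpha))
    loc = np.asarray(mean, dtype=float) / inflation
    return stats.truncnorm.ppf(stats.norm.cdf(z), alpha, np.inf, loc=loc, scale=loc * cv)


@dataclass(frozen=True)
class VarianceModel:
    """Which variances enter the draws, and how large they are."""

    process_cv: float = 0.05
    use_sampling: bool = True

    def __post_init__(self):
        if self.process_cv < 0:
            raise ValueError("process_cv must be non-negative")

    @staticmethod
    def _ci_sd(ci) -> float:
        if ci is None or ci[0] is None:
            return 0.0
        return (ci[1] - ci[0]) / 3.92

    def sampling_sd(self, rates: VitalRates) -> dict[str, float]:
        if not self.use_sampling:
            return {"s3": 0.0, "transient": 0.0}
        return {"s3": self._ci_sd(rates.s3_ci), "transient": self._ci_sd(rates.transient_ci)}

    def fecundity_cv(self, rates: VitalRates) -> float:
        """CV of eggs/female/season propagated from the printed SDs.

        Fecundity dispersion is a process-variance component: it is
        switched off together with ``process_cv`` so a zero-variance model
        is exactly deterministic.
        """
        if self.process_cv == 0 or rates.clutch_size_sd is None or rates.ecf_sd is None:
            return 0.0
        return float(
            np.hypot(rates.clutch_size_sd / rates.clutch_size, rates.ecf_sd / rates.ecf)
        )

    def validate(self, rates: VitalRates) -> None:
        for name, sd in self.sampling_sd(rates).items():
            m = getattr(rates, name)
            if sd > 0 and sd**2 >= m * (1 - m):
                raise ValueError(f"sampling variance of {name} exceeds beta bound")
        probs = {
            "s1": rates.s1, "s2": rates.s2, "s3": rates.s3,
            "b1": rates.b1, "b2": rates.b2, "b3": rates.b3, "b4": rates.b4,
            "transient": rates.transient,
            "egg_to_water": rates.egg_to_water, "sex_ratio": rates.sex_ratio,
        }
        for name, m in probs.items():
            v = (m * self.process_cv) ** 2
            if v > 0 and 0 < m < 1 and v >= m * (1 - m):
                raise ValueError(
                    f"process variance of {name} (mean {m}) exceeds the beta bound mean*(1-mean)"
                )


def sample_vital_rates(
    rates: VitalRates, variance: VarianceModel, rng: np.random.Generator
) -> VitalRates:
    """One joint draw of the stochastic vital rates (survivals and
    proportions from betas, fecundity from a truncated normal)."""
    variance.validate(rates)
    cv = variance.process_cv
    z = rng.standard_normal(len(_Z_KEYS))
    samp = variance.sampling_sd(rates)

    def draw(zk, mean, extra_sd=0.0):
        sd = np.hypot(mean * cv, extra_sd)
        return float(beta_from_normal(np.array(z[_Z_KEYS.index(zk)]), mean, sd))

    f_cv = variance.fecundity_cv(rates)
    f = float(truncnorm_fecundity(z[_Z_KEYS.index("f")], rates.eggs_per_season, f_cv))
    return rates.with_(
        s1=draw("s1", rates.s1),
        s2=draw("s2", rates.s2),
        s3=draw("s3", rates.s3, samp["s3"]),
        b1=draw("b1", rates.b1),
        b2=draw("b2", rates.b2),
        b3=draw("b3", rates.b3),
        b4=draw("b4", rates.b4),
        transient=draw("transient", rates.transient, samp["transient"]),
        eggs_per_season=f,
        clutch_size=None,
        ecf=None,
        survival_to_water=draw("stw", rates.egg_to_water),
        sex_ratio=draw("fem", rates.sex_ratio),
    )


@dataclass(frozen=True)
class StochasticSpec:
    """Monte-Carlo design: replicate count, horizon, variances, extinction."""

    n_trajectories: int = 1000
    horizon: int = 100
    variance: VarianceModel = field(default_factory=VarianceModel)
    seed: int = 0
    quasi_extinction_threshold: float = 1.0
    extinction_stages: tuple[str, ...] = LATE_STAGES
    initial: str = "observed"  # or "ssd"
    breeders: float = DEFAULT_BREEDERS
    duration_rule: str = "age_expanded"

    def __post_init__(self):
        if self.n_trajectories < 1 or self.horizon < 1:
            raise ValueError("n_trajectories and horizon must be >= 1")
        if self.quasi_extinction_threshold < 0:
            raise ValueError("quasi-extinction threshold must be >= 0")


@dataclass
class TrajectoryEnsemble:
    """Stage-aggregated abundance, shape (trajectory, year, 16 stages)."""

    abundance: np.ndarray
    spec: StochasticSpec
    seed: int
    matrix: ProjectionMatrix

    def __post_init__(self):
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be non-negative")

    def total(self) -> np.ndarray:
        return self.abundance.sum(axis=-1)

    def pool(self, stages=None) -> np.ndarray:
        stages = stages or self.spec.extinction_stages
        idx = [i for i, lab in enumerate(self.matrix.stage_labels()) if lab.split("_")[0] in stages]
        return self.abundance[..., idx].sum(axis=-1)


@dataclass
class ProjectionResult:
    lambda_s: float
    ci_low: float
    ci_high: float
    p_extinction: float
    t_extinction_median: Optional[float]
    label: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.lambda_s <= self.ci_high) or not 0 <= self.p_extinction <= 1:
            raise ValueError("inconsistent projection result")


def initial_vector(pm: ProjectionMatrix, params: SubpopulationSet, spec: StochasticSpec) -> np.ndarray:
    """Starting abundance per matrix class.

    ``"observed"`` places the annual breeders (split by nesting share) in
    the Breeder stages and the female hatchlings they produce in the
    yearling stage; ``"ssd"`` scales the block stable stage distributions
    to the same breeder counts.
    """
    x = np.zeros(pm.n_classes)
    shares = params.block_shares
    if spec.initial == "ssd":
        w = mixture_ssd(pm, params).values
        b = w[pm.stage_mask(["B"])].sum()
        return w / b * spec.breeders
    if spec.initial != "observed":
        raise ValueError(f"unknown initial vector rule: {spec.initial!r}")
    for block in BLOCKS:
        rates = getattr(params, block)
        breeders = spec.breeders * shares[block]
        b_idx = np.flatnonzero(pm.stage_mask(["B"], block))
        y_idx = np.flatnonzero(pm.stage_mask(["Y"], block))
        x[b_idx[0]] = breeders
        # female hatchlings reaching the water, produced by those breeders
        x[y_idx[0]] = breeders * rates.eggs_per_season * rates.egg_to_water * rates.sex_ratio
    return x


def _scenario_hooks(scenario):
    if scenario is None:
        return (lambda year: 1.0), (lambda block: 1.0), None, 0.98
    return (
        scenario.s3_multiplier,
        scenario.hatchling_multiplier,
        scenario.headstart_cohort(),
        getattr(scenario, "survival_cap", 0.98),
    )


def _year_params(block_rates, z, s3_traj, tr_traj, cv, f_cv, s3_mult, hmul, cap):
    """Vectorised yearly draw for one block; returns assemble_block params
    plus hatchling production per breeder."""
    n = s3_traj.shape[0]

    def pdraw(key, mean):
        return beta_from_normal(z[_Z_KEYS.index(key)], mean, np.asarray(mean) * cv)

    s3m = np.clip(s3_traj * s3_mult, 1e-9, cap)
    s3 = beta_from_normal(z[_Z_KEYS.index("s3")], s3m, s3m * cv)
    tr = beta_from_normal(z[_Z_KEYS.index("transient")], tr_traj, tr_traj * cv)
    f = truncnorm_fecundity(z[_Z_KEYS.index("f")], np.full(n, float(block_rates.eggs_per_season)), f_cv)
    stw = pdraw("stw", block_rates.egg_to_water)
    fem = pdraw("fem", block_rates.sex_ratio)
    s1 = pdraw("s1", block_rates.s1)
    params = {
        "F": f * stw * fem * s1 * hmul,
        "S2": pdraw("s2", block_rates.s2),
        "S3": s3,
        "B1": pdraw("b1", block_rates.b1),
        "B2": pdraw("b2", block_rates.b2),
        "B3": pdraw("b3", block_rates.b3),
        "B4": pdraw("b4", block_rates.b4),
        "Tr": tr,
    }
    return params, f * stw, fem, s1


def project_ensemble(
    params: SubpopulationSet,
    spec: StochasticSpec,
    scenario=None,
    seed: Optional[int] = None,
) -> TrajectoryEnsemble:
    """Run the Monte-Carlo ensemble; deterministic given (spec, seed)."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    for block in BLOCKS:
        spec.variance.validate(getattr(params, block))
    pm = build_projection_matrix(params, spec.duration_rule)
    n, T = spec.n_trajectories, spec.horizon
    s3_mult, hatch_mult, headstart, cap = _scenario_hooks(scenario)

    x0 = initial_vector(pm, params, spec)
    C = pm.scheme.classes_per_block
    x = {
        block: np.tile(x0[pm.block_slice(block)], (n, 1)) for block in BLOCKS
    }
    # trajectory-level (sampling) draws, independent between blocks
    traj = {}
    for block in BLOCKS:
        r = getattr(params, block)
        samp = spec.variance.sampling_sd(r)
        traj[block] = {
            "s3": _sample_level(rng, r.s3, samp["s3"], n),
            "tr": _sample_level(rng, r.transient, samp["transient"], n),
        }

    agg = _aggregator(pm)
    out = np.zeros((n, T + 1, 16))
    for block in BLOCKS:
        out[:, 0] += x[block] @ agg[block]
    y_col = {b: int(np.flatnonzero(pm.stage_mask(["Y"], b))[0] - pm.block_slice(b).start) for b in BLOCKS}
    b_col = {b: int(np.flatnonzero(pm.stage_mask(["B"], b))[0] - pm.block_slice(b).start) for b in BLOCKS}

    for t in range(1, T + 1):
        z = rng.standard_normal((len(_Z_KEYS), n))  # shared environment
        for block in BLOCKS:
            r = getattr(params, block)
            p, prod_rate, fem, s1 = _year_params(
                r, z, traj[block]["s3"], traj[block]["tr"],
                spec.variance.process_cv, spec.variance.fecundity_cv(r),
                s3_mult(t), hatch_mult(block), cap,
            )
            A = assemble_block(p, spec.duration_rule)
            produced = x[block][:, b_col[block]] * prod_rate  # both-sex hatchlings
            x[block] = np.einsum("nij,nj->ni", A, x[block])
            if headstart is not None and block == "costa_rica":
                n_head, release_surv, net = headstart
                cohort = np.minimum(n_head, produced)
                gain = cohort * fem * release_surv
                if net:
                    gain -= cohort * fem * s1
                x[block][:, y_col[block]] += np.maximum(gain, -x[block][:, y_col[block]])
            out[:, t] += x[block] @ agg[block]
    return TrajectoryEnsemble(abundance=out, spec=spec, seed=seed, matrix=pm)


def _sample_level(rng, mean, sd, n):
    if sd <= 0:
        return np.full(n, float(mean))
    var = min(sd**2, 0.999 * mean * (1 - mean))
    a, b = _beta_ab(np.asarray(mean, dtype=float), var)
    return rng.beta(a, b, size=n)


def _aggregator(pm: ProjectionMatrix) -> dict[str, np.ndarray]:
    """Per-block (C, 16) matrices summing classes into the 16 stages."""
    C = pm.scheme.classes_per_block
    s = pm.scheme.block_stage_of_class()
    agg = {}
    for i, block in enumerate(BLOCKS):
        M = np.zeros((C, 16))
        for c in range(C):
            M[c, 8 * i + s[c]] = 1.0
        agg[block] = M
    return agg


def deterministic_projection(
    params: SubpopulationSet, scenario=None, spec: StochasticSpec | None = None
) -> dict:
    """Projection at exact mean rates (a single noise-free trajectory).

    Returns the realized mean annual growth rate over the horizon (the
    headline deterministic lambda), the asymptotic dominant eigenvalue, and
    the quasi-extinction year.
    """
    spec = spec or StochasticSpec()
    det_spec = replace(
        spec, n_trajectories=1, variance=VarianceModel(process_cv=0.0, use_sampling=False)
    )
    ens = project_ensemble(params, det_spec, scenario=scenario, seed=0)
    tot = ens.total()[0]
    lam = float((tot[-1] / tot[0]) ** (1.0 / spec.horizon))
    pool = ens.pool()[0]
    below = np.flatnonzero(pool < spec.quasi_extinction_threshold)
    pm = build_projection_matrix(params, spec.duration_rule)
    from .matrix_model import deterministic_lambda as _dl

    return {
        "lambda": lam,
        "lambda_asymptotic": _dl(pm),
        "extinction_year": int(below[0]) if below.size else None,
        "total": tot,
        "ensemble": ens,
    }


def stochastic_lambda(ens: TrajectoryEnsemble) -> tuple[float, float, float]:
    """lambda_s with its 95% CI across trajectories.

    Per-trajectory mean annual log growth of total females, exponentiated;
    the CI is the 2.5/97.5 percentile range of the per-trajectory rates.
    """
    tot = ens.total()
    if tot.shape[1] < 2:
        raise ValueError("ensemble must span at least two years")
    if np.any(tot[:, 0] <= 0):
        raise ValueError("ensemble starts at zero abundance")
    logs = np.log(tot[:, 1:] / tot[:, :-1])
    per_traj = np.exp(logs.mean(axis=1))
    lam = float(np.exp(logs.mean()))
    lo, hi = np.percentile(per_traj, [2.5, 97.5])
    return lam, float(lo), float(hi)


def extinction_metrics(
    ens: TrajectoryEnsemble, threshold: Optional[float] = None, reporting_floor: float = 0.005
) -> dict:
    """Quasi-extinction probability and median time to extinction.

    A trajectory is extinct at the first year the monitored pool (default:
    subadult + adult females) falls below the threshold.  The median year
    is undefined (None) when the extinct fraction is below the reporting
    floor, mirroring the dashes of published scenario tables.
    """
    threshold = ens.spec.quasi_extinction_threshold if threshold is None else threshold
    pool = ens.pool()
    below = pool < threshold
    any_ext = below.any(axis=1)
    p = float(any_ext.mean())
    if p < reporting_floor:
        return {"p_extinction": p, "t_extinction_median": None, "t_extinction": np.array([])}
    years = below[any_ext].argmax(axis=1)
    return {
        "p_extinction": p,
        "t_extinction_median": float(np.median(years)),
        "t_extinction": years,
    }


def project_result(ens: TrajectoryEnsemble, label: str = "") -> ProjectionResult:
    lam, lo, hi = stochastic_lambda(ens)
    ext = extinction_metrics(ens)
    return ProjectionResult(
        lambda_s=lam,
        ci_low=lo,
        ci_high=hi,
        p_extinction=ext["p_extinction"],
        t_extinction_median=ext["t_extinction_median"],
        label=label,
    )
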