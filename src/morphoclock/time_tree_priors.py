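"""Priors on node ages and branch rates for relaxed-clock dating.

Three independent components multiply into the joint prior:

* a birth--death process with incomplete species sampling (Stadler 2009)
  on the uncalibrated divergence times, conditioned on the number of tips
  and the root age;
* an uncorrelated lognormal relaxed clock (Drummond et al. 2006): each
  branch rate is an independent LogNormal(m, s) draw;
* soft normal fossil-calibration densities on the ages of selected clades
  (means and standard deviations in Ma).

A nine-calibration table for placental-mammal dating, with normal priors
whose 95% interval spans the minimum/maximum divergence ages recommended
by the fossil-calibration survey of Benton et al. (2015), ships as a
packaged fixture (:func:`mammal_calibrations`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from .trees import TimeTree, TreeError

__all__ = [
    "ClockModel",
    "BirthDeathParams",
    "CalibrationPrior",
    "ucln_log_prior",
    "birth_death_log_prior",
    "calibration_log_prior",
    "resolve_mrca",
    "mammal_calibrations",
    "read_calibration_table",
    "write_calibration_table",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class ClockModel:
    """Uncorrelated lognormal clock: per-branch rates and hyperparameters.

    ``m`` is the log-scale location and ``s >= 0`` the log-scale spread of
    the branch-rate lognormal (s = 0 degenerates to a strict clock at
    exp(m)); rates are in expected changes per character per Myr.
    """

    m: float
    s: float
    rates: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("lognormal spread s must be >= 0")
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.size and self.rates.min() <= 0:
            raise ValueError("branch rates must be positive")


@dataclass(frozen=True)
class BirthDeathParams:
    """Speciation/extinction/sampling parameters of the tree prior."""

    birth: float
    death: float = 0.0
    sampling: float = 1.0

    def __post_init__(self) -> None:
        if self.birth <= 0:
            raise ValueError("speciation rate must be > 0")
        if not 0 <= self.death < self.birth:
            raise ValueError("need 0 <= extinction < speciation")
        if not 0 < self.sampling <= 1:
            raise ValueError("sampling fraction must be in (0, 1]")


@dataclass(frozen=True)
class CalibrationPrior:
    """Normal prior on the age of the MRCA of a taxon set."""

    name: str
    taxa: frozenset[str]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("calibration sd must be > 0")


def ucln_log_prior(rates: np.ndarray, m: float, s: float) -> float:
    """Sum of independent LogNormal(m, s) log-densities of branch rates."""
    rates = np.asarray(rates, dtype=float)
    if s <= 0:
        raise ValueError("s must be > 0 for a proper lognormal density")
    if rates.size == 0:
        return 0.0
    if rates.min() <= 0:
        return -np.inf
    lr = np.log(rates)
    return float(
        np.sum(-lr - np.log(s) - _LOG_SQRT_2PI - 0.5 * ((lr - m) / s) ** 2)
    )


# ---------------------------------------------------------------------------
# birth-death with species sampling


def _bd_log_p1(t: np.ndarray, p: BirthDeathParams) -> np.ndarray:
    """log p1(t): probability density that a lineage of age t leaves
    exactly one sampled descendant (Stadler 2009)."""
    lam, mu, rho = p.birth, p.death, p.sampling
    r = lam - mu
    d = rho * lam + (lam * (1 - rho) - mu) * np.exp(-r * np.asarray(t, float))
    return np.log(rho) + 2 * np.log(r) - r * np.asarray(t, float) - 2 * np.log(d)


def _bd_p1_integral(T: float, p: BirthDeathParams) -> float:
    """Closed form of the integral of p1 over (0, T)."""
    lam, mu, rho = p.birth, p.death, p.sampling
    r = lam - mu
    a = rho * lam
    b = lam * (1 - rho) - mu
    if abs(b) < 1e-12 * lam:
        return r * (1.0 - np.exp(-r * T)) / (rho * lam * lam)
    d0 = a + b
    dT = a + b * np.exp(-r * T)
    return (rho * r / b) * (1.0 / dT - 1.0 / d0)


def _bd_quantile(u: float, T: float, p: BirthDeathParams) -> float:
    """Inverse CDF of the single-node age density p1(t)/F(T) on (0, T)."""
    lam, mu, rho = p.birth, p.death, p.sampling
    r = lam - mu
    a = rho * lam
    b = lam * (1 - rho) - mu
    if abs(b) < 1e-12 * lam:
        return -np.log1p(-u * (1.0 - np.exp(-r * T))) / r
    target = 1.0 / (a + b) + u * _bd_p1_integral(T, p) * b / (rho * r)
    x = (1.0 / target - a) / b  # = exp(-r t)
    return float(-np.log(x) / r)


def birth_death_log_prior(tree: TimeTree, params: BirthDeathParams,
                          ages: np.ndarray | None = None) -> float:
    """Log density of the non-root internal node ages.

    Under the sampled birth--death process conditioned on the root age and
    the number of tips, the n-2 non-root divergence times are independent
    draws from the density p1(t) / integral_0^t_root p1 (each of which
    integrates to one over (0, t_root)); the root age itself carries no
    density here — it is constrained only by its calibration.
    """
    a = tree.ages if ages is None else np.asarray(ages, float)
    t_root = float(a[tree.root])
    if t_root <= 0:
        return -np.inf
    nonroot = a[tree.n_tips : tree.root]
    if nonroot.size == 0:
        return 0.0
    norm = _bd_p1_integral(t_root, params)
    return float(np.sum(_bd_log_p1(nonroot, params)) - nonroot.size * np.log(norm))


# ---------------------------------------------------------------------------
# fossil calibrations


def resolve_mrca(tree: TimeTree, taxa: set[str] | frozenset[str]) -> int:
    """Node index of the MRCA of a taxon set; tips are rejected."""
    node = tree.mrca(taxa)
    if node < tree.n_tips:
        raise TreeError("calibration resolves to a tip")  # pragma: no cover
    return node


def calibration_log_prior(
    tree: TimeTree,
    calibrations: list[CalibrationPrior],
    ages: np.ndarray | None = None,
    nodes: list[int] | None = None,
) -> float:
    """Sum of normal log-densities of the calibrated node ages.

    The normals are soft (support on the whole real line); node ages are
    in practice bounded below by their children, so no truncation is
    applied.  ``nodes`` may carry pre-resolved node indices to avoid
    repeated MRCA searches.
    """
    a = tree.ages if ages is None else np.asarray(ages, float)
    if nodes is None:
        nodes = [resolve_mrca(tree, c.taxa) for c in calibrations]
    total = 0.0
    for c, v in zip(calibrations, nodes):
        z = (a[v] - c.mean) / c.sd
        total += -np.log(c.sd) - _LOG_SQRT_2PI - 0.5 * z * z
    return float(total)


# ---------------------------------------------------------------------------
# calibration tables


def read_calibration_table(path) -> pd.DataFrame:
    """Read a calibration table: name, comma-separated taxa, mean_Ma, sd_Ma."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "taxa": str})
    need = {"name", "taxa", "mean_Ma", "sd_Ma"}
    if not need <= set(df.columns):
        raise ValueError(f"calibration table {path} lacks columns {sorted(need)}")
    return df


def write_calibration_table(calibrations: list[CalibrationPrior], path) -> None:
    pd.DataFrame(
        {
            "name": [c.name for c in calibrations],
            "taxa": [",".join(sorted(c.taxa)) for c in calibrations],
            "mean_Ma": [c.mean for c in calibrations],
            "sd_Ma": [c.sd for c in calibrations],
        }
    ).to_csv(path, sep="\t", index=False)


def calibrations_from_table(df: pd.DataFrame) -> list[CalibrationPrior]:
    out = []
    for row in df.itertuples(index=False):
        taxa = frozenset(t for t in str(row.taxa).split(",") if t and t != "nan")
        out.append(CalibrationPrior(row.name, taxa, float(row.mean_Ma), float(row.sd_Ma)))
    return out


def mammal_calibrations() -> pd.DataFrame:
    """The packaged nine-row placental-mammal calibration table.

    Taxon sets are analysis-specific (they depend on the tip labels of the
    tree at hand), so the ``taxa`` column ships empty and is filled in by
    the caller or by the synthetic-replica generator.
    """
    with resources.files("morphoclock").joinpath(
        "data/mammal_calibrations.tsv"
    ).open() as fh:
        return read_calibration_table(fh)
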