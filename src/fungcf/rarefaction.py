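"""Incidence-based richness estimation for gene cluster families.

Given the GCF-by-genome incidence matrix of a group (typically a genus),
this module computes the incidence frequency counts Q_j (families detected
in exactly j genomes), the Chao2 asymptotic richness estimator, the standard
sample-size-based interpolation (rarefaction) and extrapolation of expected
richness for Hill number order q = 0, and the potential GCF count (pGCF):
the extrapolated richness at a fixed genome endpoint, by default 10,000
genomes with 500 knots along the curve.

All binomial coefficients are evaluated in log space so endpoints of 10^4
sampling units pose no overflow problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .diversity import IncidenceMatrix
from .model import ValidationError

DEFAULT_ENDPOINT = 10_000
DEFAULT_KNOTS = 500


@dataclass
class IncidenceFrequencies:
    """Incidence frequency counts over a set of sampling units (genomes)."""

    n_units: int
    s_obs: int
    q: dict[int, int]  # j -> number of GCFs detected in exactly j units

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValidationError("n_units must be >= 1")
        if sum(self.q.values()) != self.s_obs:
            raise ValidationError("sum of Q_j must equal s_obs")
        if any(j < 1 or j > self.n_units for j in self.q):
            raise ValidationError("incidence counts j must lie in [1, n_units]")

    @property
    def q1(self) -> int:
        return self.q.get(1, 0)

    @property
    def q2(self) -> int:
        return self.q.get(2, 0)


def frequencies(matrix: IncidenceMatrix, group: Sequence[str]) -> IncidenceFrequencies:
    """Frequency counts over the submatrix restricted to ``group`` genomes."""
    group = list(group)
    if not group:
        raise ValidationError("empty genome group")
    missing = set(group) - set(matrix.genome_ids)
    if missing:
        raise ValidationError(f"genomes not in matrix: {sorted(missing)[:5]}")
    sub = matrix.df[group]
    counts = sub.sum(axis=1).to_numpy()
    q: dict[int, int] = {}
    for c in counts:
        c = int(c)
        if c > 0:
            q[c] = q.get(c, 0) + 1
    return IncidenceFrequencies(n_units=len(group), s_obs=int(sum(q.values())), q=q)


def chao2(freq: IncidenceFrequencies) -> float:
    """Chao2 asymptotic richness (incidence data, with the bias-corrected
    branch when no duplicates are observed)."""
    n = freq.n_units
    s, q1, q2 = freq.s_obs, freq.q1, freq.q2
    if q2 > 0:
        return s + (n - 1) / n * q1 * q1 / (2.0 * q2)
    return s + (n - 1) / n * q1 * (q1 - 1) / 2.0


def _log_comb(n: float, k: float) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def rarefy(freq: IncidenceFrequencies, t: int) -> float:
    """Expected richness in a random subset of ``t`` of the n units:
    S_obs - sum_j Q_j * C(n-j, t) / C(n, t)."""
    n = freq.n_units
    if not 1 <= t <= n:
        raise ValidationError(f"t must lie in [1, {n}]")
    deficit = 0.0
    log_cnt = _log_comb(n, t)
    for j, qj in freq.q.items():
        if n - j >= t:
            deficit += qj * np.exp(_log_comb(n - j, t) - log_cnt)
    return freq.s_obs - deficit


def extrapolate(freq: IncidenceFrequencies, t_star: int) -> float:
    """Expected richness ``t_star`` units beyond the observed n:
    S_obs + Q0_hat * [1 - (1 - Q1 / (n*Q0_hat + Q1))^t_star]."""
    if t_star < 0:
        raise ValidationError("t_star must be >= 0")
    if t_star == 0:
        return float(freq.s_obs)
    q1 = freq.q1
    q0_hat = chao2(freq) - freq.s_obs
    if q1 == 0 or q0_hat <= 0:
        return float(freq.s_obs)
    n = freq.n_units
    ratio = q1 / (n * q0_hat + q1)
    return freq.s_obs + q0_hat * (1.0 - (1.0 - ratio) ** t_star)


@dataclass
class RarefactionCurve:
    """Interpolated/extrapolated richness knots plus the endpoint estimate."""

    group: str
    knots: list[tuple[int, float]]
    endpoint: int
    pgcf: float
    s_obs: int
    chao2: float


def curve(
    matrix: IncidenceMatrix,
    group: Sequence[str],
    endpoint: int = DEFAULT_ENDPOINT,
    n_knots: int = DEFAULT_KNOTS,
    label: str = "",
) -> RarefactionCurve:
    """Sample-size-based rarefaction/extrapolation curve for one group."""
    freq = frequencies(matrix, group)
    n = freq.n_units
    if endpoint < n:
        warnings.warn(
            f"endpoint {endpoint} < n_units {n}; raised to {n}", stacklevel=2
        )
        endpoint = n
    ts = np.round(np.linspace(1, endpoint, n_knots)).astype(int)
    knots = []
    for t in ts.tolist():
        est = rarefy(freq, t) if t <= n else extrapolate(freq, t - n)
        knots.append((t, float(est)))
    pgcf = rarefy(freq, endpoint) if endpoint <= n else extrapolate(freq, endpoint - n)
    return RarefactionCurve(
        group=label,
        knots=knots,
        endpoint=endpoint,
        pgcf=float(pgcf),
        s_obs=freq.s_obs,
        chao2=chao2(freq),
    )


def promising_genera(
    pgcf_by_genus: Mapping[str, float], np_counts: Mapping[str, float]
) -> list[str]:
    """Genera whose known-compound count is (strictly) below 10% of their
    potential GCF count — candidates with untapped biosynthetic diversity."""
    flagged = []
    for genus in sorted(pgcf_by_genus):
        if genus not in np_counts:
            warnings.warn(f"no NP count for genus {genus}; treated as 0", stacklevel=2)
        np_count = np_counts.get(genus, 0)
        if np_count < 0.1 * pgcf_by_genus[genus]:
            flagged.append(genus)
    return flagged
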