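"""Similarity mathematics: KL divergence, Jensen-Shannon divergence and distance.

For two probability mass functions S and T over shared bins x,

    DKL(S || T) = sum_x S(x) * log( S(x) / T(x) )
    M           = (S + T) / 2
    DJS(S || T) = DKL(S || M) / 2 + DKL(T || M) / 2
    JSD(S, T)   = sqrt( DJS(S || T) )

With base-2 logarithms both DJS and JSD are bounded in [0, 1]; JSD is a
metric (symmetric, identity of indiscernibles, triangle inequality).  A
JSD of 0 means the distributions are identical, a JSD of 1 that they
share no support.

Two support-alignment conventions are offered.  ``union`` keeps every bin
where either distribution has mass, with the 0*log(0) = 0 convention;
this is the convention under which the 0/1 bounds hold exactly (two
disjoint distributions reach JSD = 1).  ``shared`` keeps only bins where
both distributions are non-zero, optionally renormalizing the retained
masses; it is provided because some audits restrict the sum to bins with
mass in both comparison groups.  Every result records which convention
and log base produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import rel_entr

from .cohort import CategoricalDistribution

UNION = "union"
SHARED = "shared"

_IDENTITY_TOL = 1e-12


class EmptySupportError(ValueError):
    """Support alignment removed every bin (disjoint supports under ``shared``)."""


class InfiniteDivergenceError(ValueError):
    """DKL is infinite: T(x) = 0 on a bin where S(x) > 0."""


@dataclass(frozen=True)
class SupportPolicy:
    """How bins with zero mass are handled before divergence summation."""

    mode: str = UNION
    renormalize_after_exclusion: bool = False

    def __post_init__(self) -> None:
        if self.mode not in (UNION, SHARED):
            raise ValueError(f"support policy mode must be union|shared, got {self.mode!r}")


@dataclass(frozen=True)
class DivergenceResult:
    """KL/JS divergence values with the conventions that produced them."""

    dkl_s_m: float
    dkl_t_m: float
    djs: float
    jsd: float
    log_base: float
    support_policy: SupportPolicy
    bins_used: tuple[str, ...] = ()
    bins_excluded: tuple[str, ...] = ()


def _as_masses(dist: CategoricalDistribution | Sequence[float]) -> np.ndarray:
    if isinstance(dist, CategoricalDistribution):
        return dist.masses
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("masses must be a non-empty 1-D vector")
    if np.any(arr < 0):
        raise ValueError("masses must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("masses must have positive total")
    return arr / total


def _labels_of(
    dist: CategoricalDistribution | Sequence[float], n: int
) -> tuple[str, ...]:
    if isinstance(dist, CategoricalDistribution):
        return dist.labels
    return tuple(f"bin_{i}" for i in range(n))


def align_supports(
    S: CategoricalDistribution | Sequence[float],
    T: CategoricalDistribution | Sequence[float],
    policy: SupportPolicy = SupportPolicy(),
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Align two distributions onto a common support per ``policy``.

    Returns ``(s, t, bins_used, bins_excluded)``.  Alignment is by label
    (T is reindexed onto S's label order); bare mass vectors are aligned
    positionally.  ``union`` keeps bins where S(x) + T(x) > 0; ``shared``
    keeps bins where both are positive, renormalizing the retained masses
    only when the policy says so.
    """
    s = _as_masses(S)
    if isinstance(S, CategoricalDistribution) and isinstance(T, CategoricalDistribution):
        if set(S.labels) != set(T.labels):
            raise ValueError(
                f"label sets differ: {sorted(set(S.labels) ^ set(T.labels))}"
            )
        T = T.reindexed(S.labels)
    t = _as_masses(T)
    if s.shape != t.shape:
        raise ValueError(f"distributions have {s.size} vs {t.size} bins")
    labels = _labels_of(S, s.size)

    if policy.mode == UNION:
        keep = (s + t) > 0
    else:
        keep = (s > 0) & (t > 0)
    if not keep.any():
        raise EmptySupportError(
            "no common support bin remains under the shared-support policy"
        )
    excluded = tuple(lab for lab, k in zip(labels, keep) if not k)
    used = tuple(lab for lab, k in zip(labels, keep) if k)
    s, t = s[keep], t[keep]
    if policy.mode == SHARED and policy.renormalize_after_exclusion:
        s = s / s.sum()
        t = t / t.sum()
    return s, t, used, excluded


def kl_divergence(
    S: Sequence[float] | CategoricalDistribution,
    T: Sequence[float] | CategoricalDistribution,
    log_base: float = 2,
) -> float:
    """Kullback-Leibler divergence sum_x S(x) log(S(x)/T(x)).

    Bins with S(x) = 0 contribute 0 (the 0*log 0 convention); a bin with
    T(x) = 0 where S(x) > 0 makes the divergence infinite and raises
    :class:`InfiniteDivergenceError`.  Inputs may be counts; they are
    normalized to masses first.
    """
    s = _as_masses(S)
    t = _as_masses(T)
    if s.shape != t.shape:
        raise ValueError(f"distributions have {s.size} vs {t.size} bins")
    terms = rel_entr(s, t)  # nats; inf where s>0, t=0
    if np.isinf(terms).any():
        bad = int(np.argmax(np.isinf(terms)))
        raise InfiniteDivergenceError(
            f"T has zero mass at bin index {bad} where S has mass {s[bad]:.6g}"
        )
    return float(terms.sum() / math.log(log_base))


def js_divergence(
    S: CategoricalDistribution | Sequence[float],
    T: CategoricalDistribution | Sequence[float],
    log_base: float = 2,
    policy: SupportPolicy = SupportPolicy(),
) -> DivergenceResult:
    """Jensen-Shannon divergence DJS = DKL(S||M)/2 + DKL(T||M)/2, M = (S+T)/2.

    M is formed after support alignment, so every bin with S(x) > 0 or
    T(x) > 0 has M(x) > 0 and the KL terms are finite by construction.
    Symmetric in (S, T); the returned result also carries the distance
    ``jsd = sqrt(djs)``.
    """
    s, t, used, excluded = align_supports(S, T, policy)
    m = (s + t) / 2.0
    dkl_s_m = kl_divergence(s, m, log_base)
    dkl_t_m = kl_divergence(t, m, log_base)
    djs = 0.5 * dkl_s_m + 0.5 * dkl_t_m
    djs = max(djs, 0.0)  # guard tiny negative rounding
    return DivergenceResult(
        dkl_s_m=dkl_s_m,
        dkl_t_m=dkl_t_m,
        djs=djs,
        jsd=math.sqrt(djs),
        log_base=log_base,
        support_policy=policy,
        bins_used=used,
        bins_excluded=excluded,
    )


def jsd(
    S: CategoricalDistribution | Sequence[float],
    T: CategoricalDistribution | Sequence[float],
    log_base: float = 2,
    policy: SupportPolicy = SupportPolicy(),
) -> DivergenceResult:
    """Jensen-Shannon distance sqrt(DJS); in [0, 1] for log base 2 + union."""
    return js_divergence(S, T, log_base=log_base, policy=policy)


def ppr(
    subgroup_participant_fraction: float,
    subgroup_reference_fraction: float,
) -> float:
    """Participant-to-prevalence ratio for a single demographic subgroup.

    The ratio of the subgroup's share among study participants to its
    share of the reference population (disease prevalence); 1 indicates
    proportional representation.  Complementary to the JSD: the JSD
    summarizes a whole category, the PPR examines one subgroup.
    """
    if not (0 < subgroup_participant_fraction <= 1):
        raise ValueError(
            f"participant fraction must be in (0, 1], got {subgroup_participant_fraction}"
        )
    if not (0 < subgroup_reference_fraction <= 1):
        raise ValueError(
            f"reference fraction must be in (0, 1] and non-zero, "
            f"got {subgroup_reference_fraction}"
        )
    return subgroup_participant_fraction / subgroup_reference_fraction
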