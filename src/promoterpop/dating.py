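"""Homozygosity-tract-length statistics and time estimation from mutation
counts and sequence divergence.

A homozygosity tract length (HTL) is the bp span over which a pair of carrier
haplotypes stays identical outward from a core interval; because recombination
erodes shared tracts at rate r per bp per generation, the mean HTL converts to
an age as t = g / (k * r * mean_HTL) with k = 1 (one-sided scan) or 2 (both
sides).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .panel_io import GenomicRegion
from .params import EvoParams


@dataclass
class HTLSummary:
    side: str  # upstream | downstream | both
    pair_labels: list[tuple[str, str]]
    lengths: np.ndarray  # bp, one per carrier pair
    mean: float


def _pair_tract_length(
    a: np.ndarray,
    b: np.ndarray,
    positions: np.ndarray,
    window: GenomicRegion,
    core: tuple[int, int],
    side: str,
) -> float:
    ok = (a != "N") & (b != "N")
    mism = positions[ok & (a != b)]
    lo, hi = core
    up = mism[mism < lo]
    down = mism[mism > hi]
    upstream = lo - (up.max() if up.size else window.start - 1) - 1
    downstream = (down.min() if down.size else window.end + 1) - hi - 1
    if side == "upstream":
        return float(upstream)
    if side == "downstream":
        return float(downstream)
    if side == "both":
        return float(upstream + downstream)
    raise ValueError(f"unknown side {side!r}")


def homozygosity_tract_lengths(
    carrier_ids,
    carrier_seqs,
    positions,
    window: GenomicRegion,
    core: tuple[int, int],
    side: str = "upstream",
) -> HTLSummary:
    """Pairwise HTLs among carriers, measured from the core boundary to the
    first pairwise mismatch on the requested side (window edge if none)."""
    ids = list(carrier_ids)
    seqs = [np.asarray(list(s) if isinstance(s, str) else s, dtype="<U1") for s in carrier_seqs]
    if len(ids) < 2:
        raise ValueError("need at least two carriers")
    positions = np.asarray(positions, dtype=np.int64)
    pairs, lengths = [], []
    for i, j in itertools.combinations(range(len(ids)), 2):
        pairs.append((ids[i], ids[j]))
        lengths.append(
            _pair_tract_length(seqs[i], seqs[j], positions, window, core, side)
        )
    lengths = np.asarray(lengths)
    return HTLSummary(side, pairs, lengths, float(lengths.mean()))


def htl_to_age(mean_htl: float, params: EvoParams, k: int = 1) -> float:
    """Age in years from a mean HTL: t = g / (k * r * mean_HTL).

    ``k`` is 1 for a one-sided tract scan and 2 when upstream and downstream
    tracts were pooled.
    """
    if mean_htl <= 0:
        raise ValueError("mean HTL must be positive")
    if k not in (1, 2):
        raise ValueError("k must be 1 (one-sided) or 2 (two-sided)")
    return params.g / (k * params.r * mean_htl)


def expected_pairwise_differences(
    t_split: float, mu: float, length: float, *, rounded: bool = False
) -> float:
    """Expected site differences between lineages split t years: 2 * t * mu * L."""
    if t_split < 0 or mu <= 0 or length <= 0:
        raise ValueError("t_split must be >= 0; mu and length positive")
    value = 2.0 * t_split * mu * length
    return float(round(value)) if rounded else float(value)


@dataclass
class CladeMutationSummary:
    """Observed mutation count on a star genealogy of a clade."""

    s: int  # derived mutations accumulated within the clade
    n_lineages: int  # branches the mutations are summed over
    length: float  # sequence length in bp
    mu: float  # per site per year

    def __post_init__(self) -> None:
        if self.s < 0 or int(self.s) != self.s:
            raise ValueError("mutation count must be a nonnegative integer")
        if self.n_lineages < 1 or self.length <= 0 or self.mu <= 0:
            raise ValueError("n_lineages, length and mu must be positive")


def poisson_ml_tmrca(summary: CladeMutationSummary) -> tuple[float, tuple[float, float]]:
    """Maximum-likelihood clade age from Poisson mutation counts.

    With S mutations over n star branches of length t years each,
    S ~ Poisson(n * L * mu * t), so t_hat = S / (n * L * mu) and the 95% CI is
    the normal approximation t_hat * (1 +/- 1.96 / sqrt(S)), truncated at 0.
    For S = 0 the upper bound comes from the exact Poisson tail.
    """
    rate = summary.n_lineages * summary.length * summary.mu  # mutations/year
    if summary.s == 0:
        upper = -np.log(0.025) / rate  # P(S=0 | t) >= 2.5% boundary
        return 0.0, (0.0, float(upper))
    t_hat = summary.s / rate
    half = 1.96 / np.sqrt(summary.s)
    return float(t_hat), (float(max(0.0, t_hat * (1 - half))), float(t_hat * (1 + half)))
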