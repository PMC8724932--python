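"""Decoy ("mock") transcript database and the binomial empirical p-value.

The null model: random genomic segments matching the real transcript DB's
size (segment length = the mean transcript length) are six-frame translated
and searched with the same peptides. The observed decoy match count m sets
the per-candidate chance-match probability

    p = m / (n_decoy_segments x frames x segment_len / peptide_len_nt)

and the significance of k observed matches among the real DB's
n = n_transcripts x (frames x mean_len / peptide_len_nt) candidate peptides
is the upper binomial tail P(X >= k), evaluated in log space.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class DecoyConfig:
    n_segments: int = 50_000
    segment_len_nt: int = 2_000
    seed: int = 0
    exclude_N: bool = True

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.segment_len_nt < 33:
            raise ValueError("segment_len_nt must be >= 33")


def generate_decoy_segments(
    genome: Sequence[tuple[str, str]], config: DecoyConfig
) -> list[tuple[str, int, int]]:
    """Sample non-overlapping fixed-length segments uniformly from the genome.

    Rejection sampling of uniform start positions; segments overlapping an
    already-accepted segment (or containing N, when ``exclude_N``) are
    resampled. Deterministic for a given seed. Output sorted by (chrom, start).
    """
    seg = config.segment_len_nt
    total = sum(len(seq) for _, seq in genome)
    required = config.n_segments * seg
    if total < required:
        raise ValueError(
            f"genome too small: {total} nt available, "
            f"{required} nt required for {config.n_segments} x {seg} nt segments"
        )
    chroms = [(name, seq) for name, seq in genome if len(seq) >= seg]
    weights = np.array([len(seq) - seg + 1 for _, seq in chroms], dtype=float)
    cum = np.cumsum(weights)
    rng = np.random.default_rng(config.seed)
    taken: dict[str, list[int]] = {name: [] for name, _ in chroms}  # sorted starts
    out: list[tuple[str, int, int]] = []
    attempts = 0
    max_attempts = 200 * config.n_segments + 10_000
    while len(out) < config.n_segments:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.n_segments} non-overlapping segments "
                f"after {max_attempts} attempts; genome too crowded"
            )
        # chromosome chosen with probability proportional to its usable
        # start positions, then a uniform start within it: uniform overall
        u = rng.uniform(0, cum[-1])
        ci = int(np.searchsorted(cum, u, side="right"))
        name, seq = chroms[ci]
        start = int(rng.integers(0, len(seq) - seg + 1))
        starts = taken[name]
        i = bisect_left(starts, start)
        if i > 0 and starts[i - 1] + seg > start:
            continue
        if i < len(starts) and start + seg > starts[i]:
            continue
        if config.exclude_N and "N" in seq[start : start + seg]:
            continue
        insort(starts, start)
        out.append((name, start, start + seg))
    out.sort()
    return out


def segment_sequences(
    genome: Sequence[tuple[str, str]], segments: Iterable[tuple[str, int, int]]
) -> list[tuple[str, str]]:
    """FASTA-ready (id, sequence) records for decoy segments."""
    by_name = dict(genome)
    return [
        (f"decoy|{chrom}:{start}-{end}", by_name[chrom][start:end])
        for chrom, start, end in segments
    ]


def decoy_match_count(
    peptides: Iterable[str],
    decoy_records: Sequence[tuple[str, str]],
    il_equivalence: bool = True,
) -> int:
    """Number of distinct peptides with >=1 six-frame match in the decoy DB."""
    from .matching import match_peptides
    from .sixframe import build_translated_db

    db = build_translated_db(decoy_records)
    matches = match_peptides(list(peptides), db, il_equivalence=il_equivalence)
    return len({m.peptide for m in matches})


# ---------------------------------------------------------------------------
# Eq.-style chance probability and binomial upper tail
# ---------------------------------------------------------------------------


def p_chance(
    m: int, n_transcripts: int, frames: int = 6, seg_len: int = 2_000, pep_nt: int = 33
) -> float:
    """Chance probability of a single candidate-peptide match:
    m / (n_transcripts x frames x seg_len / pep_nt)."""
    if m < 0:
        raise ValueError("match count m must be >= 0")
    if min(n_transcripts, frames, seg_len, pep_nt) <= 0:
        raise ValueError("all denominator counts must be positive")
    denom = n_transcripts * frames * seg_len / pep_nt
    if denom <= 0:
        raise ValueError("zero denominator")
    if m > denom:
        raise ValueError(f"m={m} exceeds the number of candidate slots {denom:.0f}")
    return m / denom


def _log_pmf(j: np.ndarray, n: int, p: float) -> np.ndarray:
    return (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * math.log(p)
        + (n - j) * math.log1p(-p)
    )


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p).

    Evaluated in log space with log-gamma binomial coefficients; stable for
    n of order 1e7-1e9 with small p. For k at or below the mean the
    complement of the (short) lower tail is used instead.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    mean = n * p
    if k <= mean:
        # lower tail has at most ~mean terms and sums to < 0.5 here
        logs = _log_pmf(np.arange(0, k, dtype=float), n, p)
        lower = float(np.exp(logsumexp(logs)))
        return max(0.0, 1.0 - lower)
    total_log = -np.inf
    j = k
    chunk = 8192
    while j <= n:
        hi = min(n, j + chunk - 1)
        logs = _log_pmf(np.arange(j, hi + 1, dtype=float), n, p)
        total_log = np.logaddexp(total_log, logsumexp(logs))
        # above the mean the terms decrease geometrically; stop once the
        # last term can no longer move the accumulated sum
        if logs[-1] < total_log - 46.0 or hi == n:
            break
        j = hi + 1
    return float(np.exp(total_log))


@dataclass
class NullModelParams:
    """Inputs and derived quantities of the decoy null model."""

    m_decoy_matches: int
    n_decoy_transcripts: int = 50_000
    frames: int = 6
    segment_len_nt: int = 2_000
    peptide_len_nt: int = 33  # an average 11-mer is coded by 33 nt
    n_real_transcripts: int = 107_039
    mean_len_nt: int | None = None  # defaults to segment_len_nt
    k_observed: int = 0
    n_candidates: int = field(init=False)
    p_chance: float = field(init=False)

    def __post_init__(self) -> None:
        mean_len = self.mean_len_nt if self.mean_len_nt is not None else self.segment_len_nt
        self.n_candidates = round(
            self.n_real_transcripts * self.frames * mean_len / self.peptide_len_nt
        )
        self.p_chance = p_chance(
            self.m_decoy_matches,
            self.n_decoy_transcripts,
            self.frames,
            self.segment_len_nt,
            self.peptide_len_nt,
        )
        if not 0 <= self.k_observed <= self.n_candidates:
            raise ValueError("k_observed outside [0, n_candidates]")


def empirical_pvalue(params: NullModelParams) -> tuple[float, float]:
    """Chain the chance probability into the binomial upper tail:
    returns (p_chance, P(X >= k_observed))."""
    pv = binomial_tail(params.k_observed, params.n_candidates, params.p_chance)
    return params.p_chance, pv
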