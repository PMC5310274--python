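"""Foreground/background site sampling and dataset assembly.

Foreground sequences are context windows centered on observed read 5'-end
positions (sampled in proportion to read count, i.e. uniformly over the read
multiset); background sequences come from the same neighbourhoods, shifted by
a random non-zero offset, which approximately preserves local base
composition while breaking the priming signal.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneModel, Genome, ReadStartSite, extract_window

__all__ = [
    "PositionCounts",
    "ContextSequence",
    "SequenceDataset",
    "count_read_starts",
    "sample_foreground_sites",
    "sample_background_sites",
    "extract_context_sequences",
    "split_dataset",
    "write_sequences",
    "read_sequences",
]

SiteKey = tuple[str, int, str]


@dataclass
class PositionCounts:
    """Read-start counts restricted to annotated exonic positions."""

    counts: dict[SiteKey, int]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped != sum(self.counts.values()):
            raise ValueError("total_mapped inconsistent with counts")


@dataclass(frozen=True)
class ContextSequence:
    """A 2w+1 context window tagged with its origin and source site."""

    seq: str
    origin: str  # "foreground" | "background"
    site: SiteKey


@dataclass
class SequenceDataset:
    """Disjoint train/validation/test partition of context sequences."""

    train: list[ContextSequence]
    validation: list[ContextSequence]
    test: list[ContextSequence]
    proportions: tuple[float, float, float] = (0.9, 0.05, 0.05)

    def __len__(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def _exon_index(gene_models: list[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-contig merged exon intervals as sorted (starts, ends) arrays."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in gene_models:
        by_contig.setdefault(g.contig, []).extend(g.exons)
    index = {}
    for contig, intervals in by_contig.items():
        intervals.sort()
        merged: list[list[int]] = []
        for start, end in intervals:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        arr = np.asarray(merged, dtype=np.int64)
        index[contig] = (arr[:, 0], arr[:, 1])
    return index


def count_read_starts(
    sites: list[ReadStartSite], gene_models: list[GeneModel]
) -> PositionCounts:
    """Keep sites falling inside any gene's exon; aggregate duplicate keys."""
    index = _exon_index(gene_models)
    counts: dict[SiteKey, int] = {}
    total = 0
    for site in sites:
        if site.contig not in index:
            continue
        starts, ends = index[site.contig]
        i = int(np.searchsorted(starts, site.pos, side="right")) - 1
        if i < 0 or site.pos >= ends[i]:
            continue
        counts[site.key] = counts.get(site.key, 0) + site.count
        total += site.count
    return PositionCounts(counts, total)


def sample_foreground_sites(
    counts: PositionCounts,
    n: int,
    seed: int,
    weight_by_count: bool = True,
    replace: bool = True,
) -> list[SiteKey]:
    """Draw ``n`` foreground sites, by default with replacement and with
    probability proportional to read count (sampling reads, not positions)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not counts.counts:
        raise ValueError("no exonic read-start counts to sample from")
    keys = list(counts.counts)
    rng = np.random.default_rng(seed)
    if weight_by_count:
        weights = np.fromiter(
            (counts.counts[k] for k in keys), dtype=float, count=len(keys)
        )
        p = weights / weights.sum()
    else:
        p = None
    idx = rng.choice(len(keys), size=n, replace=replace, p=p)
    return [keys[i] for i in idx]


def sample_background_sites(
    fg_sites: list[SiteKey],
    max_offset: int,
    genome: Genome,
    seed: int,
    w: int = 10,
    max_retries: int = 50,
) -> list[SiteKey]:
    """For each foreground site, a site offset by delta drawn uniformly from
    {-max_offset..-1, 1..max_offset} on the same contig/strand.

    Offsets whose 2w+1 window would leave the contig are redrawn (bounded
    retries); sites with no valid offset are dropped with a warning.
    """
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[SiteKey] = []
    n_dropped = 0
    for contig, pos, strand in fg_sites:
        clen = len(genome[contig])
        placed = False
        for _ in range(max_retries):
            k = int(rng.integers(0, 2 * max_offset))
            delta = k - max_offset if k < max_offset else k - max_offset + 1
            q = pos + delta
            if q - w >= 0 and q + w < clen:
                out.append((contig, q, strand))
                placed = True
                break
        if not placed:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} background sites with no valid offset",
            stacklevel=2,
        )
    return out


def extract_context_sequences(
    sites: list[SiteKey], genome: Genome, w: int, origin: str
) -> list[ContextSequence]:
    """Extract 2w+1 windows per site; windows hitting a contig edge or an N
    are filtered out (the boundary filter)."""
    out = []
    for site in sites:
        contig, pos, strand = site
        seq = extract_window(genome, contig, pos, strand, w)
        if seq is not None:
            out.append(ContextSequence(seq, origin, site))
    return out


def split_dataset(
    seqs: list[ContextSequence],
    proportions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
) -> SequenceDataset:
    """Shuffle under ``seed`` then split contiguously; train/validation sizes
    are rounded, the remainder goes to test."""
    props = tuple(float(p) for p in proportions)
    if len(props) != 3 or any(p <= 0 for p in props):
        raise ValueError("proportions must be three positive numbers")
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {sum(props)}, expected 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(seqs))
    shuffled = [seqs[i] for i in order]
    n = len(seqs)
    n_train = round(props[0] * n)
    n_val = round(props[1] * n)
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return SequenceDataset(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        proportions=props,
    )


def write_sequences(seqs: list[ContextSequence], path: str | os.PathLike) -> None:
    """Plain-text export: one sequence per line."""
    with open(path, "w") as out:
        for cs in seqs:
            out.write(cs.seq + "\n")


def read_sequences(path: str | os.PathLike, origin: str = "unknown") -> list[ContextSequence]:
    out = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line:
                out.append(ContextSequence(line, origin, ("", -1, "+")))
    return out
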