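"""Per-site sequence-specific bias weights from a foreground/background
model pair.

A site's bias is the ratio p_f(contextSeq)/p_b(contextSeq) of its context
window's probability under the foreground (read-start) and background
(offset) language models; read counts are later divided by it, so contexts
enriched at read starts are down-weighted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Genome, extract_window
from .rnnlm import sequence_log_prob, sequence_log_probs
from .sampling import PositionCounts, SiteKey

__all__ = ["BiasTable", "site_bias", "build_bias_table", "read_bias_table"]


@dataclass
class BiasTable:
    """Map from (contig, pos, strand) to a positive bias weight.

    Sites whose context window was undefined (contig edge or N) carry the
    neutral weight 1.0 and are listed in ``flagged``.
    """

    weights: dict[SiteKey, float]
    w: int
    flagged: set[SiteKey] = field(default_factory=set)
    fg_id: str = "foreground"
    bg_id: str = "background"

    def __post_init__(self) -> None:
        for key, value in self.weights.items():
            if not (value > 0 and np.isfinite(value)):
                raise ValueError(f"bias weight at {key} is {value}; must be finite > 0")

    def get(self, key: SiteKey, default: float = 1.0) -> float:
        return self.weights.get(key, default)

    def __len__(self) -> int:
        return len(self.weights)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as out:
            out.write("contig\tpos\tstrand\tbias\tflagged\n")
            for (contig, pos, strand), b in self.weights.items():
                flag = int((contig, pos, strand) in self.flagged)
                out.write(f"{contig}\t{pos}\t{strand}\t{b!r}\t{flag}\n")


def read_bias_table(path: str | os.PathLike, w: int = 10) -> BiasTable:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "strand": str})
    weights = {}
    flagged = set()
    for row in df.itertuples(index=False):
        key = (row.contig, int(row.pos), row.strand)
        weights[key] = float(row.bias)
        if int(row.flagged):
            flagged.add(key)
    return BiasTable(weights, w, flagged)


def site_bias(fg_model, bg_model, context_seq: str, clip: float | None = None) -> float:
    """exp(log p_f - log p_b) for one context sequence.

    ``clip`` (off by default) symmetrically clamps the ratio into
    [1/clip, clip] to guard against extreme underflow-scale ratios.
    """
    b = float(
        np.exp(sequence_log_prob(fg_model, context_seq) - sequence_log_prob(bg_model, context_seq))
    )
    if clip is not None:
        b = min(max(b, 1.0 / clip), clip)
    return b


def build_bias_table(
    fg_model,
    bg_model,
    genome: Genome,
    counts: PositionCounts,
    w: int,
    clip: float | None = None,
) -> BiasTable:
    """One bias weight per counted site, batch-scored under both models."""
    sites = list(counts.counts)
    seqs: list[str] = []
    seq_sites: list[SiteKey] = []
    flagged: set[SiteKey] = set()
    weights: dict[SiteKey, float] = {}
    for site in sites:
        contig, pos, strand = site
        window = extract_window(genome, contig, pos, strand, w)
        if window is None:
            weights[site] = 1.0
            flagged.add(site)
        else:
            seqs.append(window)
            seq_sites.append(site)
    if seqs:
        lp_fg = sequence_log_probs(fg_model, seqs)
        lp_bg = sequence_log_probs(bg_model, seqs)
        ratios = np.exp(lp_fg - lp_bg)
        if clip is not None:
            ratios = np.clip(ratios, 1.0 / clip, clip)
        for site, b in zip(seq_sites, ratios):
            weights[site] = float(b)
    # restore counted-site order
    ordered = {site: weights[site] for site in sites}
    return BiasTable(ordered, w, flagged)
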