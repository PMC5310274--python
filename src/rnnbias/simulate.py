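"""Synthetic data with a known injected sequence-specific bias.

The generator emulates the mechanism the correction targets: random-primer
selection whose efficiency depends on the nucleotide context of the read
5'-end.  The ground-truth bias is a log-linear positional weight matrix
(PWM) over the 2w+1 context window — the simplest mechanism this class of
correction methods is designed to capture, and one that admits closed-form
checks.

Reads are placed at exonic positions.  Under the default ``per_site``
scheme a read lands at position p of gene g with globally-normalized
intensity proportional to (abundance_g / exonic_length_g) * pwm_weight(p):
per-base transcript abundance times priming efficiency.  Gene-level totals
are then distorted by each gene's mean context weight, which is exactly the
bias the pipeline must remove.  The alternative ``per_gene`` scheme first
assigns each read to a gene in proportion to abundance and only then picks
a position within the gene in proportion to PWM weight; it leaves gene
totals unbiased and is useful for isolating site-level effects.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    Genome,
    ReadStartSite,
    write_fasta,
    write_gene_models,
    write_read_starts,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "pwm_weight",
    "random_pwm",
    "simulate_dataset",
    "write_sam",
]

_BASES = np.array(list("ACGT"))
_A2I = {c: i for i, c in enumerate("ACGT")}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a 100 kb contig carrying 100 non-overlapping two-exon
    genes (200 bp exons), log-normal(0, 1) relative abundances and 200 k
    reads — large enough for stable per-gene counts yet quick to simulate.
    """

    contig_name: str = "sim1"
    contig_length: int = 100_000
    n_genes: int = 100
    exons_per_gene: int = 2
    exon_size: int = 200
    intron_size: int = 150
    log_mu: float = 0.0
    log_sigma: float = 1.0
    n_reads: int = 200_000
    w: int = 10
    pwm: np.ndarray | None = None  # (2w+1, 4) log-weights; None = no bias
    seed: int = 0
    read_sampling: str = "per_site"  # "per_site" | "per_gene"

    def __post_init__(self) -> None:
        for name in ("contig_length", "n_genes", "exons_per_gene", "exon_size",
                     "intron_size", "n_reads"):
            if getattr(self, name) <= 0 and name != "intron_size":
                raise ValueError(f"{name} must be positive")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.read_sampling not in ("per_site", "per_gene"):
            raise ValueError(f"unknown read_sampling {self.read_sampling!r}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape != (2 * self.w + 1, 4):
                raise ValueError(
                    f"pwm shape {self.pwm.shape} != {(2 * self.w + 1, 4)}"
                )
            if not np.all(np.isfinite(self.pwm)):
                raise ValueError("pwm must be finite")


@dataclass
class SimResult:
    """In-memory view of one simulated dataset plus its ground truth."""

    genome: Genome
    genes: list[GeneModel]
    sites: list[ReadStartSite]
    truth: pd.DataFrame  # gene_id, abundance, exonic_length
    site_weights: pd.DataFrame  # gene_id, pos, weight
    config: SimConfig


def pwm_weight(M: np.ndarray, seq: str) -> float:
    """exp(sum_j M[j, seq_j]) — the injected selection weight of a context."""
    M = np.asarray(M, dtype=float)
    if len(seq) != M.shape[0]:
        raise ValueError(f"sequence length {len(seq)} != PWM length {M.shape[0]}")
    try:
        idx = [_A2I[ch] for ch in seq]
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in sequence") from exc
    return float(math.exp(M[np.arange(len(seq)), idx].sum()))


def random_pwm(w: int, scale: float = math.log(3.0), seed: int = 0) -> np.ndarray:
    """A random strong bias PWM: entries uniform on (-scale, +scale),
    row-centered so each position is neutral on average."""
    rng = np.random.default_rng(seed)
    M = rng.uniform(-scale, scale, size=(2 * w + 1, 4))
    return M - M.mean(axis=1, keepdims=True)


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    cursor = cfg.w + int(rng.integers(10, 100))
    for gi in range(cfg.n_genes):
        exons = []
        pos = cursor
        for _ in range(cfg.exons_per_gene):
            exons.append((pos, pos + cfg.exon_size))
            pos += cfg.exon_size + cfg.intron_size
        end = exons[-1][1]
        if end + cfg.w >= cfg.contig_length:
            raise ValueError(
                f"genes unplaceable: gene {gi} would end at {end}, "
                f"contig length {cfg.contig_length}"
            )
        genes.append(GeneModel(f"gene{gi:04d}", cfg.contig_name, "+", exons))
        cursor = end + int(rng.integers(50, 151))
    return genes


def simulate_dataset(
    config: SimConfig, outdir: str | os.PathLike | None = None, sam: bool = False
) -> SimResult:
    """Generate genome, gene models, abundances and biased read starts.

    Deterministic under ``config.seed``.  When ``outdir`` is given, writes
    ``genome.fa``, ``genes.bed``, ``read_starts.tsv``, ``truth_genes.tsv``,
    ``truth_sites.tsv`` and ``config.json`` (plus ``reads.sam`` if ``sam``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)
    codes = rng.integers(0, 4, size=cfg.contig_length)
    genome = Genome({cfg.contig_name: "".join(_BASES[codes])})
    theta = rng.lognormal(cfg.log_mu, cfg.log_sigma, size=cfg.n_genes)
    theta = theta / theta.sum()

    M = cfg.pwm if cfg.pwm is not None else np.zeros((2 * cfg.w + 1, 4))
    offsets = np.arange(-cfg.w, cfg.w + 1)
    cols = np.arange(2 * cfg.w + 1)

    gene_pos: list[np.ndarray] = []
    gene_wlog: list[np.ndarray] = []
    for g in genes:
        pos = np.concatenate([np.arange(s, e) for s, e in g.exons])
        ctx = codes[pos[:, None] + offsets[None, :]]
        gene_pos.append(pos)
        gene_wlog.append(M[cols[None, :], ctx].sum(axis=1))

    if cfg.read_sampling == "per_site":
        rates = np.concatenate(
            [
                theta[gi] / len(gene_pos[gi]) * np.exp(gene_wlog[gi])
                for gi in range(cfg.n_genes)
            ]
        )
        probs = rates / rates.sum()
        all_counts = rng.multinomial(cfg.n_reads, probs)
        counts_per_gene = np.split(
            all_counts, np.cumsum([len(p) for p in gene_pos])[:-1]
        )
    else:  # per_gene
        n_per_gene = rng.multinomial(cfg.n_reads, theta)
        counts_per_gene = []
        for gi in range(cfg.n_genes):
            wl = gene_wlog[gi]
            p = np.exp(wl - wl.max())
            counts_per_gene.append(rng.multinomial(n_per_gene[gi], p / p.sum()))

    sites: list[ReadStartSite] = []
    sw_rows = []
    for gi, g in enumerate(genes):
        pos, wlog, cnt = gene_pos[gi], gene_wlog[gi], counts_per_gene[gi]
        for p_, w_ in zip(pos, np.exp(wlog)):
            sw_rows.append((g.gene_id, int(p_), float(w_)))
        nz = np.nonzero(cnt)[0]
        for j in nz:
            sites.append(ReadStartSite(cfg.contig_name, int(pos[j]), "+", int(cnt[j])))

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "abundance": theta,
            "exonic_length": [g.length for g in genes],
        }
    )
    site_weights = pd.DataFrame(sw_rows, columns=["gene_id", "pos", "weight"])
    result = SimResult(genome, genes, sites, truth, site_weights, cfg)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(genome, os.path.join(outdir, "genome.fa"))
        write_gene_models(genes, os.path.join(outdir, "genes.bed"))
        write_read_starts(sites, os.path.join(outdir, "read_starts.tsv"))
        truth.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
        site_weights.to_csv(
            os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False
        )
        doc = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(cfg).items()
        }
        with open(os.path.join(outdir, "config.json"), "w") as out:
            json.dump(doc, out, indent=1)
        if sam:
            write_sam(result, os.path.join(outdir, "reads.sam"))
    return result


def write_sam(
    result: SimResult, path: str | os.PathLike, read_length: int = 50
) -> None:
    """Minimal single-record-per-read SAM export for the alignment path.

    Each read becomes one primary alignment whose 5'-end reproduces its
    site: forward reads start at the site, reverse reads end at it.
    """
    genome = result.genome
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.contigs.items():
            out.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        rid = 0
        for site in result.sites:
            clen = len(genome[site.contig])
            if site.strand == "+":
                rl = min(read_length, clen - site.pos)
                start = site.pos
                flag = 0
            else:
                rl = min(read_length, site.pos + 1)
                start = site.pos - rl + 1
                flag = 16
            seq = genome[site.contig][start : start + rl]
            for _ in range(site.count):
                out.write(
                    f"r{rid}\t{flag}\t{site.contig}\t{start + 1}\t255\t{rl}M"
                    f"\t*\t0\t0\t{seq}\t*\tNH:i:1\n"
                )
                rid += 1
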