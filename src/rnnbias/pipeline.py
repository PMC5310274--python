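"""End-to-end convenience driver: simulated data in, corrected FPKM out.

Chains the library stages (count -> sample -> train fg/bg -> bias table ->
quantify) with one seed, mirroring what the CLI does across files but in
memory.  Used by integration tests and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import sampling
from .bias import BiasTable, build_bias_table
from .quantify import quantify
from .rnnlm import NucleotideRNN, RNNResults
from .simulate import SimResult

__all__ = ["PipelineResult", "correct_simulated"]


@dataclass
class PipelineResult:
    counts: sampling.PositionCounts
    fg_results: RNNResults
    bg_results: RNNResults
    bias_table: BiasTable
    expression: pd.DataFrame  # joined with truth abundance
    fg_dataset: sampling.SequenceDataset
    bg_dataset: sampling.SequenceDataset


def correct_simulated(
    sim: SimResult,
    n_sequences: int = 4000,
    max_offset: int = 30,
    unit: str = "gru",
    hidden: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> PipelineResult:
    """Run the full correction pipeline on one simulated dataset.

    ``fit_kwargs`` are passed to :meth:`NucleotideRNN.fit` (epochs,
    optimizer, learning_rate, ...); the seed derives every stage's
    randomness.
    """
    w = sim.config.w
    counts = sampling.count_read_starts(sim.sites, sim.genes)
    fg_sites = sampling.sample_foreground_sites(counts, n_sequences, seed=seed)
    bg_sites = sampling.sample_background_sites(
        fg_sites, max_offset, sim.genome, seed=seed + 1, w=w
    )
    fg_seqs = sampling.extract_context_sequences(fg_sites, sim.genome, w, "foreground")
    bg_seqs = sampling.extract_context_sequences(bg_sites, sim.genome, w, "background")
    fg_ds = sampling.split_dataset(fg_seqs, seed=seed + 2)
    bg_ds = sampling.split_dataset(bg_seqs, seed=seed + 3)
    fit_kwargs.setdefault("seed", seed)
    fg_res = NucleotideRNN.from_dataset(fg_ds, unit=unit, hidden=hidden).fit(**fit_kwargs)
    bg_res = NucleotideRNN.from_dataset(bg_ds, unit=unit, hidden=hidden).fit(**fit_kwargs)
    table = build_bias_table(fg_res, bg_res, sim.genome, counts, w)
    expr = quantify(counts, sim.genes, table)
    expr = expr.merge(sim.truth[["gene_id", "abundance"]], on="gene_id")
    return PipelineResult(counts, fg_res, bg_res, table, expr, fg_ds, bg_ds)
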