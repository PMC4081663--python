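"""Bundled reference data and synthetic-data generators.

The two machine-readable fixtures ship inside the package:

* :func:`table1_matrix` — the published 4 x 10 NF-κB p50 mutation matrix
  (reference site GGGACTTTCC), measured on a bimolecular dsDNA microarray.
* :func:`table2_dataset` — 52 10-bp sequences with their EMSA log values,
  PC / SNMM / PWMSA / Match model scores and PBM z-scores (41 sequences
  have a z-score; the rest are missing).

:func:`simulate_microarray` emulates the structure of the mutation-panel
microarray experiment (31 probes in replicate, Gaussian intensity noise) so
matrix construction can be tested end to end; :func:`nfkb_pwm` builds a
stand-in NF-κB p50 position weight matrix from the highest-affinity
published sites for the comparator scorers.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import (
    PWM,
    SITE_WIDTH,
    IntensityTable,
    MutationMatrix,
    build_pwm,
    read_snmm,
)
from .seqs import BASES

__all__ = [
    "table1_matrix",
    "table2_dataset",
    "nfkb_pwm",
    "simulate_microarray",
    "random_10mers",
    "load_selex_table",
]

MODEL_COLUMNS = ("PC", "SNMM", "PWMSA", "Match")


def _data_path(name: str):
    return resources.files("snmmkit.data") / name


def table1_matrix() -> MutationMatrix:
    """The published single-nucleotide mutation matrix (reference GGGACTTTCC)."""
    with resources.as_file(_data_path("snmm_table1.tsv")) as p:
        return read_snmm(p)


def table2_dataset() -> pd.DataFrame:
    """52 sites with EMSA log values, model scores and (41) PBM z-scores.

    Columns: sequence, EMSA, PC, SNMM, PWMSA, Match, PBM; missing PBM
    entries are NaN.  Values are exactly as published (3-dp scores).
    """
    with resources.as_file(_data_path("table2_affinities.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col])
    return df


def nfkb_pwm(n_sites: int = 30, pseudocount: float = 1.0) -> PWM:
    """A stand-in NF-κB p50 PWM built from the published high-affinity sites.

    Synthetic in the sense that it is constructed by this package — the
    original SELEX-derived TRANSFAC count matrix is not redistributed here —
    by tallying the ``n_sites`` highest-EMSA sequences of the bundled
    affinity table.  It captures the canonical GGGRNNYYCC motif well enough
    to drive Match-based rejection sampling of non-sites.
    """
    df = table2_dataset().sort_values(
        ["EMSA", "sequence"], ascending=[False, True], kind="stable"
    )
    sites = df["sequence"].head(n_sites).tolist()
    return build_pwm(sites, pseudocount=pseudocount, name=f"nfkb-p50-top{n_sites}")


def simulate_microarray(
    matrix: MutationMatrix,
    base_intensity: float = 1000.0,
    noise_sd: float = 2.0,
    replicates: int = 3,
    rng_seed: int | np.random.Generator = 0,
) -> IntensityTable:
    """Simulate a mutation-panel microarray readout for a known matrix.

    The reference probe draws ``replicates`` intensities from
    Normal(base_intensity, noise_sd); each of the 30 single-base mutants
    draws from Normal(base_intensity + delta cell, noise_sd).  Negative
    draws are truncated at 0 with a warning.  With ``noise_sd=0`` the
    readout inverts exactly back to ``matrix`` through ``build_snmm``.

    The Gaussian error model is a synthetic convenience for testing
    parameter recovery; it is not a calibrated model of scanner noise.
    """
    if base_intensity <= 0:
        raise ValueError("base_intensity must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ref = matrix.reference
    probes: dict[str, list[float]] = {}
    truncated = 0

    def draw(mean: float) -> list[float]:
        nonlocal truncated
        vals = rng.normal(mean, noise_sd, size=replicates) if noise_sd > 0 else np.full(
            replicates, mean
        )
        truncated += int((vals < 0).sum())
        return np.clip(vals, 0.0, None).tolist()

    probes[ref] = draw(base_intensity)
    for pos in range(SITE_WIDTH):
        for base in BASES:
            if base == ref[pos]:
                continue
            mutant = ref[:pos] + base + ref[pos + 1:]
            probes[mutant] = draw(base_intensity + matrix.cell(base, pos + 1))
    if truncated:
        warnings.warn(
            f"{truncated} simulated intensities fell below 0 and were truncated",
            stacklevel=2,
        )
    return IntensityTable(ref, probes)


def random_10mers(
    n: int,
    rng_seed: int | np.random.Generator = 0,
    weights=None,
) -> list[str]:
    """n i.i.d. random 10-mers over ACGT (optionally base-weighted)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    p = None
    if weights is not None:
        p = np.asarray(
            [weights[b] for b in BASES] if isinstance(weights, dict) else list(weights),
            dtype=float,
        )
        p = p / p.sum()
    draws = rng.choice(4, size=(n, SITE_WIDTH), p=p)
    return ["".join(BASES[i] for i in row) for row in draws]


def load_selex_table(
    path: str | Path,
    sequence_column: str = "sequence",
    value_column: str = "enrichment",
) -> pd.DataFrame:
    """Load a user-supplied SELEX-Seq 10-mer enrichment TSV.

    The large-scale enrichment table is not redistributed with the package;
    this loader accepts it (tab-separated, one 10-mer and one fold-enrichment
    value per row, header optional) for re-scoring and correlation analysis.
    """
    df = pd.read_csv(path, sep="\t")
    if sequence_column not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=[sequence_column, value_column])
    df[sequence_column] = df[sequence_column].astype(str).str.upper()
    bad = df[~df[sequence_column].str.fullmatch(f"[ACGT]{{{SITE_WIDTH}}}")]
    if len(bad):
        raise ValueError(
            f"{len(bad)} rows are not {SITE_WIDTH}-mers over ACGT, "
            f"e.g. {bad[sequence_column].iloc[0]!r}"
        )
    df[value_column] = pd.to_numeric(df[value_column])
    return df
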