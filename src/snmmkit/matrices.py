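"""Matrix models of NF-κB p50 binding specificity.

Two matrix types live here:

* :class:`MutationMatrix` — the single-nucleotide mutation matrix (SNMM):
  a 4 x 10 grid of binding-affinity differences between a 10-bp reference
  site and each of its 30 single-base mutants, measured on a double-stranded
  DNA microarray.  Cells are in normalized signal-intensity units; the
  reference base at every position sits at 0 by construction.
* :class:`PWM` — a classical position count/frequency matrix with a
  background model and a per-column information vector, used by the
  comparator scorers (log-odds "PWMSA" and the Match matrix similarity
  score).

Construction (:func:`build_snmm`, :func:`build_pwm`), file I/O
(:func:`read_snmm` / :func:`write_snmm` in a simple TSV dialect,
:func:`read_transfac` for TRANSFAC flat-file count matrices) and the
scoring-range summaries :func:`s_min` / :func:`s_max` are all defined here.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .seqs import BASES, BASE_INDEX, canonical_seq

SITE_WIDTH = 10

__all__ = [
    "SITE_WIDTH",
    "MutationMatrix",
    "PWM",
    "IntensityTable",
    "MatrixError",
    "build_snmm",
    "s_min",
    "s_max",
    "read_snmm",
    "write_snmm",
    "read_intensity_table",
    "write_intensity_table",
    "build_pwm",
    "read_transfac",
]


class MatrixError(ValueError):
    """Structural or validation failure in a matrix or intensity table."""


# ---------------------------------------------------------------------------
# MutationMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationMatrix:
    """Single-nucleotide mutation matrix for a 10-bp binding site.

    Parameters
    ----------
    reference : str
        The 10-bp reference (wild-type) site; its base at each position is
        the normalization anchor, so the corresponding cell is 0.
    delta : ndarray of shape (4, 10)
        Affinity difference (mutant minus reference signal intensity) for
        each base (rows in A, C, G, T order) at each position (columns 1-10).
    name : str
        Free-text label.

    Notes
    -----
    Cells may be NaN only for a deliberately degraded matrix built with
    ``missing="nan"`` in :func:`build_snmm`; scoring rejects such cells.
    """

    reference: str
    delta: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        ref = canonical_seq(self.reference, length=SITE_WIDTH)
        object.__setattr__(self, "reference", ref)
        d = np.asarray(self.delta, dtype=float)
        if d.shape != (4, SITE_WIDTH):
            raise MatrixError(
                f"delta must be 4 x {SITE_WIDTH} (A,C,G,T rows), got shape {d.shape}"
            )
        if np.isinf(d).any():
            raise MatrixError("delta contains non-finite (inf) values")
        for pos, base in enumerate(ref):
            v = d[BASE_INDEX[base], pos]
            if not np.isfinite(v) or abs(v) > 1e-9:
                raise MatrixError(
                    f"reference-base cell ({base}, position {pos + 1}) must be 0, "
                    f"got {v!r}: the reference sequence anchors the normalization"
                )
        d = d.copy()
        d.setflags(write=False)
        object.__setattr__(self, "delta", d)

    @property
    def s_min(self) -> float:
        """Sum over positions of the lowest cell in each column."""
        return float(np.nansum(np.nanmin(self.delta, axis=0)))

    @property
    def s_max(self) -> float:
        """Sum over positions of the highest cell in each column."""
        return float(np.nansum(np.nanmax(self.delta, axis=0)))

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.delta).any()

    def cell(self, base: str, position: int) -> float:
        """Cell value for ``base`` at 1-based ``position``."""
        if not 1 <= position <= SITE_WIDTH:
            raise IndexError(f"position must be in 1..{SITE_WIDTH}, got {position}")
        return float(self.delta[BASE_INDEX[canonical_seq(base, length=1)], position - 1])

    def argmax_sequence(self) -> str:
        """Per-column highest-scoring 10-mer (ties: first of A<C<G<T)."""
        return "".join(BASES[i] for i in np.argmax(self.delta, axis=0))

    def argmin_sequence(self) -> str:
        """Per-column lowest-scoring 10-mer (ties: first of A<C<G<T)."""
        return "".join(BASES[i] for i in np.argmin(self.delta, axis=0))


def s_min(matrix: MutationMatrix) -> float:
    """Sum of the lowest cell at each position — the worst possible score sum."""
    return matrix.s_min


def s_max(matrix: MutationMatrix) -> float:
    """Sum of the highest cell at each position — the best possible score sum."""
    return matrix.s_max


# ---------------------------------------------------------------------------
# Intensity tables and SNMM construction
# ---------------------------------------------------------------------------


@dataclass
class IntensityTable:
    """Raw microarray signal intensities for a reference probe and its mutants.

    ``probes`` maps each 10-mer probe sequence to its replicate intensities
    (non-negative reals, typically a triplicate).  A complete table holds the
    reference plus all 30 single-nucleotide mutants: 31 distinct probes.
    """

    reference: str
    probes: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reference = canonical_seq(self.reference, length=SITE_WIDTH)
        clean: dict[str, list[float]] = {}
        for seq, reps in self.probes.items():
            s = canonical_seq(seq, length=SITE_WIDTH)
            reps = [float(v) for v in reps]
            if not reps:
                raise MatrixError(f"probe {s} has no replicate intensities")
            if s in clean and clean[s] != reps:
                raise MatrixError(
                    f"duplicate probe {s} with conflicting replicate values"
                )
            clean[s] = reps
        self.probes = clean

    def mutation_of(self, probe: str) -> tuple[str, int] | None:
        """(base, 1-based position) if ``probe`` is a single mutant, None if reference.

        Raises :class:`MatrixError` for anything else.
        """
        diffs = [i for i, (a, b) in enumerate(zip(probe, self.reference)) if a != b]
        if not diffs:
            return None
        if len(diffs) == 1:
            return probe[diffs[0]], diffs[0] + 1
        raise MatrixError(
            f"probe {probe} differs from reference {self.reference} at "
            f"{len(diffs)} positions; only single-nucleotide mutants are allowed"
        )


_AGGREGATORS: dict[str, Callable[[Sequence[float]], float]] = {
    "mean": statistics.fmean,
    "median": statistics.median,
}


def build_snmm(
    intensities: IntensityTable,
    reference: str | None = None,
    *,
    aggregator: str = "mean",
    missing: str = "error",
    name: str = "",
) -> MutationMatrix:
    """Construct a :class:`MutationMatrix` from raw probe intensities.

    Each cell is the aggregated replicate intensity of the mutant probe minus
    that of the reference probe; reference-base cells are exactly 0.

    Parameters
    ----------
    intensities : IntensityTable
        Replicate intensities; must contain the reference probe and only
        single-nucleotide mutants of it.
    reference : str, optional
        Override the table's reference sequence (must then match its probes).
    aggregator : {"mean", "median"}
        Replicate aggregation; arithmetic mean by default.
    missing : {"error", "nan", "impute_min"}
        Policy for absent mutant probes.  ``"error"`` (default) lists every
        missing probe; ``"nan"`` leaves NaN sentinels that scoring rejects;
        ``"impute_min"`` conservatively fills each gap with its column
        minimum among observed cells.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    if missing not in ("error", "nan", "impute_min"):
        raise ValueError('missing must be "error", "nan" or "impute_min"')
    if reference is not None:
        intensities = IntensityTable(reference, intensities.probes)
    ref = intensities.reference
    agg = _AGGREGATORS[aggregator]
    if ref not in intensities.probes:
        raise MatrixError(f"reference probe {ref} absent from the intensity table")
    ref_level = agg(intensities.probes[ref])

    delta = np.full((4, SITE_WIDTH), np.nan)
    for pos, base in enumerate(ref):
        delta[BASE_INDEX[base], pos] = 0.0
    for probe, reps in intensities.probes.items():
        mut = intensities.mutation_of(probe)
        if mut is None:
            continue
        base, position = mut
        # round at well below instrument resolution: suppresses binary
        # cancellation noise from the large common baseline intensity
        delta[BASE_INDEX[base], position - 1] = round(agg(reps) - ref_level, 6)

    gaps = np.argwhere(np.isnan(delta))
    if gaps.size and missing == "error":
        absent = [
            ref[:pos] + BASES[bi] + ref[pos + 1:] for bi, pos in gaps.tolist()
        ]
        raise MatrixError(
            f"incomplete mutant panel: {len(absent)} probe(s) missing: "
            + ", ".join(sorted(absent))
        )
    if gaps.size and missing == "impute_min":
        col_min = np.nanmin(delta, axis=0)
        for bi, pos in gaps.tolist():
            delta[bi, pos] = col_min[pos]
        name = name or "imputed"
    return MutationMatrix(ref, delta, name=name)


# ---------------------------------------------------------------------------
# SNMM TSV dialect
# ---------------------------------------------------------------------------
# Plain TSV: "#reference=..." (and optional "#name=...") comment lines, a
# header row numbering the positions 1..10, then one row per base A,C,G,T.


def write_snmm(matrix: MutationMatrix, path: str | Path) -> None:
    """Write a matrix in the SNMM TSV dialect (lossless at 2+ decimals)."""
    lines = [f"#reference={matrix.reference}"]
    if matrix.name:
        lines.append(f"#name={matrix.name}")
    lines.append("base\t" + "\t".join(str(i) for i in range(1, SITE_WIDTH + 1)))
    for bi, base in enumerate(BASES):
        cells = (_fmt_cell(v) for v in matrix.delta[bi])
        lines.append(base + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt_cell(v: float) -> str:
    if np.isnan(v):
        return "nan"
    short = f"{v:.2f}"
    if float(short) == v:
        return short
    return np.format_float_positional(v, unique=True, trim="0")


def read_snmm(path: str | Path) -> MutationMatrix:
    """Read a matrix from the SNMM TSV dialect, validating shape and anchors."""
    reference = None
    name = ""
    rows: dict[str, np.ndarray] = {}
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key.strip() == "reference":
                reference = value.strip()
            elif key.strip() == "name":
                name = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            got = fields[1:]
            want = [str(i) for i in range(1, SITE_WIDTH + 1)]
            if got != want:
                raise MatrixError(
                    f"{path}:{lineno}: expected header positions 1..{SITE_WIDTH}, "
                    f"got {len(got)} column(s): {got}"
                )
            header_seen = True
            continue
        base = fields[0].strip().upper()
        if base not in BASE_INDEX:
            raise MatrixError(f"{path}:{lineno}: unknown base label {fields[0]!r}")
        if len(fields) - 1 != SITE_WIDTH:
            raise MatrixError(
                f"{path}:{lineno}: row {base} has {len(fields) - 1} cells, "
                f"expected {SITE_WIDTH}"
            )
        try:
            rows[base] = np.array([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise MatrixError(f"{path}:{lineno}: non-numeric cell in row {base}: {exc}")
    if reference is None:
        raise MatrixError(f"{path}: missing '#reference=' comment line")
    if set(rows) != set(BASES):
        raise MatrixError(
            f"{path}: expected rows A,C,G,T, got {sorted(rows) or 'none'}"
        )
    return MutationMatrix(reference, np.stack([rows[b] for b in BASES]), name=name)


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    """Write probe intensities as TSV (probe, rep1..repK)."""
    lines = [f"#reference={table.reference}"]
    for probe, reps in table.probes.items():
        lines.append(probe + "\t" + "\t".join(repr(v) for v in reps))
    Path(path).write_text("\n".join(lines) + "\n")


def read_intensity_table(path: str | Path) -> IntensityTable:
    """Read a probe-intensity TSV written by :func:`write_intensity_table`."""
    reference = None
    probes: dict[str, list[float]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key.strip() == "reference":
                reference = value.strip()
            continue
        fields = line.split("\t")
        probes[fields[0]] = [float(v) for v in fields[1:]]
    if reference is None:
        raise MatrixError(f"{path}: missing '#reference=' comment line")
    return IntensityTable(reference, probes)


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PWM:
    """Position count/frequency matrix with background and information vector.

    ``counts`` and ``frequencies`` are (4, width) arrays in A,C,G,T row
    order; each frequency column sums to 1 (after any pseudocount applied at
    construction).  ``information`` holds the per-column information content
    I(i) = sum_b f(b,i) * ln(4 f(b,i)) in nats; the Match similarity score is
    invariant to the logarithm base, so nats are used throughout.
    """

    counts: np.ndarray
    frequencies: np.ndarray
    background: np.ndarray
    information: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        freqs = np.asarray(self.frequencies, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        info = np.asarray(self.information, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise MatrixError(f"counts must be 4 x width, got shape {counts.shape}")
        if (counts < 0).any():
            raise MatrixError("counts must be non-negative")
        if freqs.shape != counts.shape:
            raise MatrixError("frequencies shape must match counts")
        if not np.allclose(freqs.sum(axis=0), 1.0, atol=1e-9):
            raise MatrixError("every frequency column must sum to 1 (within 1e-9)")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise MatrixError("background must be 4 probabilities summing to 1")
        if info.shape != (counts.shape[1],) or (info < -1e-12).any():
            raise MatrixError("information must be a non-negative per-column vector")
        for arr, attr in ((counts, "counts"), (freqs, "frequencies"),
                          (bg, "background"), (info, "information")):
            arr = arr.copy()
            arr.setflags(write=False)
            object.__setattr__(self, attr, arr)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def argmax_sequence(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=0))

    def argmin_sequence(self) -> str:
        return "".join(BASES[i] for i in np.argmin(self.frequencies, axis=0))


def _information_vector(frequencies: np.ndarray) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return np.clip(term.sum(axis=0), 0.0, None)


def build_pwm(
    aligned_sequences: Iterable[str],
    pseudocount: float = 1.0,
    background: Mapping[str, float] | Sequence[float] | None = None,
    *,
    name: str = "",
) -> PWM:
    """Build a :class:`PWM` from equal-length aligned binding sites.

    frequencies = (count + pseudocount * background) / (N + pseudocount);
    the default background is uniform 0.25 and the default pseudocount 1
    (Laplace, spread by background).
    """
    seqs = [canonical_seq(s) for s in aligned_sequences]
    if not seqs:
        raise MatrixError("need at least one aligned sequence")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise MatrixError("aligned sequences must all have the same length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = _as_background(background)
    counts = np.zeros((4, width))
    for s in seqs:
        for pos, base in enumerate(s):
            counts[BASE_INDEX[base], pos] += 1.0
    n = float(len(seqs))
    freqs = (counts + pseudocount * bg[:, None]) / (n + pseudocount)
    return PWM(counts, freqs, bg, _information_vector(freqs), name=name)


def _as_background(
    background: Mapping[str, float] | Sequence[float] | None,
) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    if isinstance(background, Mapping):
        bg = np.array([float(background[b]) for b in BASES])
    else:
        bg = np.asarray(list(background), dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise MatrixError("background must be 4 probabilities summing to 1")
    return bg


def read_transfac(
    path: str | Path,
    pseudocount: float = 1.0,
    background: Mapping[str, float] | Sequence[float] | None = None,
) -> PWM:
    """Parse a TRANSFAC flat-file count matrix into a :class:`PWM`.

    Expects the classic dialect: optional header lines, a ``P0  A  C  G  T``
    column header, numbered count rows (01, 02, ...), and a ``//``
    terminator.  Frequencies are derived with the given pseudocount and
    background exactly as in :func:`build_pwm`.
    """
    lines = Path(path).read_text().splitlines()
    name = ""
    order = None
    rows: list[list[float]] = []
    row_numbers: list[int] = []
    terminated = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        tag = line.split()[0]
        if tag in ("ID", "NA", "AC"):
            parts = line.split(None, 1)
            if len(parts) > 1 and not name:
                name = parts[1]
            continue
        if tag == "P0" or tag == "PO":
            order = line.split()[1:5]
            if sorted(order) != sorted(BASES):
                raise MatrixError(
                    f"{path}:{lineno}: P0 header must list A C G T, got {order}"
                )
            continue
        if tag == "//":
            terminated = True
            break
        if tag[0].isdigit():
            if order is None:
                raise MatrixError(f"{path}:{lineno}: count row before a P0 header")
            fields = line.split()
            num = int(fields[0])
            if row_numbers and num <= row_numbers[-1]:
                raise MatrixError(
                    f"{path}:{lineno}: non-monotone row number {num} after "
                    f"{row_numbers[-1]}"
                )
            row_numbers.append(num)
            try:
                rows.append([float(v) for v in fields[1:5]])
            except ValueError as exc:
                raise MatrixError(f"{path}:{lineno}: non-numeric count: {exc}")
            continue
        # XX separators, CC comments and any other tags are skipped.
    if order is None:
        raise MatrixError(f"{path}: missing 'P0 A C G T' column header")
    if not terminated:
        raise MatrixError(f"{path}: missing '//' terminator")
    if not rows:
        raise MatrixError(f"{path}: no count rows found")
    by_base = {b: i for i, b in enumerate(order)}
    counts = np.array(rows).T[[by_base[b] for b in BASES], :]
    n = counts.sum(axis=0)
    if not np.allclose(n, n[0]):
        n = n.astype(float)  # ragged totals are legal in TRANSFAC; normalize per column
    bg = _as_background(background)
    freqs = (counts + pseudocount * bg[:, None]) / (n + pseudocount)
    freqs = freqs / freqs.sum(axis=0, keepdims=True)
    return PWM(counts, freqs, bg, _information_vector(freqs), name=name)
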