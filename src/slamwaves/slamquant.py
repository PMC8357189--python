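"""Conversion-aware SLAM-seq quantification.

Metabolic RNA labeling with 4-thiouridine (s4U) followed by iodoacetamide
alkylation makes nascent transcripts readable as T>C mismatches against the
reference. This module turns aligned reads over 3'-anchored counting windows
into labeled/total count matrices:

1. genomic variants (SNPs masquerading as conversions) are masked by their
   pooled mismatch fraction across all samples of the experiment;
2. T>C conversions are counted per read, strand-aware (reference A read as G
   for minus-strand genes);
3. a read is called *labeled* when it carries at least ``min_conversions_labeled``
   conversions at unmasked convertible positions;
4. per-window conversion rates are the unweighted mean, over unmasked
   convertible positions with coverage, of per-position conversions/coverage.

Reads are held as per-window byte matrices (``0`` = position not covered by
the read) so every per-read statistic is a vectorised column/row reduction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("slamwaves")

_A, _C, _G, _T = (ord(b) for b in "ACGT")

#: forward-strand (base read as) pairs implementing strand-aware T>C detection:
#: plus-strand genes convert reference T -> C; minus-strand genes convert the
#: transcribed-strand T, which on the reference forward strand is A -> G.
CONVERSION_BY_STRAND = {"+": (_T, _C), "-": (_A, _G)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantConfig:
    """Quantification thresholds.

    variant_fraction_threshold
        A position whose pooled mismatch fraction is >= this value (inclusive)
        at sufficient coverage is masked as a variant. Default 0.2.
    min_conversions_labeled
        Minimum unmasked T>C conversions for a read to count as labeled.
        Default 2.
    min_coverage_for_variant_call
        Minimum pooled coverage before a position may be masked. Default 10.
    min_base_coverage_for_rate
        Minimum per-sample coverage for a position to enter the per-window
        conversion-rate mean. Default 1.
    """

    variant_fraction_threshold: float = 0.2
    min_conversions_labeled: int = 2
    min_coverage_for_variant_call: int = 10
    min_base_coverage_for_rate: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.variant_fraction_threshold <= 1.0):
            raise ValueError(
                "variant_fraction_threshold must lie in (0, 1], got "
                f"{self.variant_fraction_threshold}"
            )
        if self.min_conversions_labeled < 1:
            raise ValueError("min_conversions_labeled must be >= 1")
        if self.min_coverage_for_variant_call < 1:
            raise ValueError("min_coverage_for_variant_call must be >= 1")


# ---------------------------------------------------------------------------
# read container
# ---------------------------------------------------------------------------

@dataclass
class Window:
    """A counting window: the 3'-anchored interval reads are tallied over."""

    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window {self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"window {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowReads:
    """Reads of one sample falling in one window, as a byte matrix.

    ``matrix[i, j]`` is the base (ASCII uint8) read ``i`` observed at window
    offset ``j``; 0 marks positions the read does not cover.
    """

    read_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or len(self.read_ids) != self.matrix.shape[0]:
            raise ValueError("matrix must be (n_reads, window_length)")


@dataclass
class AlignedReadSet:
    """All reads of one sample, indexed by counting window (gene id)."""

    sample_id: str
    windows: dict[str, WindowReads] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(w.matrix.shape[0] for w in self.windows.values())


def _window_index(windows: Sequence[Window]) -> dict[str, list[Window]]:
    by_contig: dict[str, list[Window]] = {}
    for w in windows:
        by_contig.setdefault(w.contig, []).append(w)
    for lst in by_contig.values():
        lst.sort(key=lambda w: w.start)
    return by_contig


def _assign_read(
    contig: str, start: int, seq: str, by_contig: Mapping[str, list[Window]]
) -> tuple[Window, int, str] | None:
    """Locate the window a read overlaps; clip the read to the overlap.

    Returns (window, offset-within-window, clipped sequence) or None when the
    read overlaps no window.
    """
    end = start + len(seq)
    for w in by_contig.get(contig, ()):  # windows are sparse; linear scan per contig
        if start < w.end and end > w.start:
            lo = max(start, w.start)
            hi = min(end, w.end)
            return w, lo - w.start, seq[lo - start : hi - start]
    return None


def _build_readset(
    sample_id: str,
    records: Iterable[tuple[str, str, int, str]],
    windows: Sequence[Window],
) -> AlignedReadSet:
    by_contig = _window_index(windows)
    per_window: dict[str, tuple[list[str], list[tuple[int, bytes]]]] = {
        w.gene_id: ([], []) for w in windows
    }
    lengths = {w.gene_id: w.length for w in windows}
    n_dropped = 0
    for read_id, contig, start, seq in records:
        hit = _assign_read(contig, start, seq, by_contig)
        if hit is None:
            n_dropped += 1
            continue
        w, off, clipped = hit
        ids, rows = per_window[w.gene_id]
        ids.append(read_id)
        rows.append((off, clipped.upper().encode("ascii")))
    if n_dropped:
        logger.warning("%s: %d reads overlap no counting window; dropped",
                       sample_id, n_dropped)
    out: dict[str, WindowReads] = {}
    for gene_id, (ids, rows) in per_window.items():
        if not ids:
            continue
        mat = np.zeros((len(ids), lengths[gene_id]), dtype=np.uint8)
        for i, (off, raw) in enumerate(rows):
            mat[i, off : off + len(raw)] = np.frombuffer(raw, dtype=np.uint8)
        out[gene_id] = WindowReads(ids, mat)
    return AlignedReadSet(sample_id, out)


def read_sam(path: str | Path, windows: Sequence[Window],
             sample_id: str | None = None) -> AlignedReadSet:
    """Load a (plain-text) SAM file into an :class:`AlignedReadSet`."""
    import pysam

    path = Path(path)
    sample_id = sample_id or path.stem
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            records.append(
                (aln.query_name, aln.reference_name, aln.reference_start,
                 aln.query_sequence)
            )
    return _build_readset(sample_id, records, windows)


def read_tsv_reads(path: str | Path, windows: Sequence[Window],
                   sample_id: str | None = None) -> AlignedReadSet:
    """Load the tabular read dialect (read_id, contig, start, strand, sequence)."""
    path = Path(path)
    sample_id = sample_id or path.stem
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    records = (
        (r.read_id, r.contig, int(r.start), r.sequence)
        for r in df.itertuples(index=False)
    )
    return _build_readset(sample_id, records, windows)


# ---------------------------------------------------------------------------
# variant masking
# ---------------------------------------------------------------------------

@dataclass
class VariantMask:
    """Positions excluded from conversion accounting, with their evidence.

    ``masked[gene_id]`` is a boolean vector over window offsets;
    ``fractions`` tabulates every masked position's pooled mismatch fraction.
    """

    masked: dict[str, np.ndarray]
    fractions: pd.DataFrame

    def positions(self) -> set[tuple[str, int]]:
        """Masked positions as (contig, absolute 0-based position)."""
        return {
            (r.contig, int(r.position))
            for r in self.fractions.itertuples(index=False)
        }

    @classmethod
    def empty(cls, windows: Sequence[Window]) -> "VariantMask":
        return cls(
            {w.gene_id: np.zeros(w.length, dtype=bool) for w in windows},
            pd.DataFrame(columns=["contig", "position", "gene_id",
                                  "coverage", "mismatch_fraction"]),
        )


def _window_ref(reference: Mapping[str, np.ndarray], w: Window) -> np.ndarray:
    seq = reference[w.contig]
    return np.asarray(seq[w.start : w.end], dtype=np.uint8)


def detect_variants(
    samples: Mapping[str, AlignedReadSet] | Iterable[AlignedReadSet],
    reference: Mapping[str, np.ndarray],
    windows: Sequence[Window],
    config: QuantConfig = QuantConfig(),
) -> VariantMask:
    """Call the experiment-wide variant mask from pooled mismatch fractions.

    All samples of the experiment are pooled (a SNP is a property of the
    genotype, not of a sample); any position whose mismatch fraction is
    ``>= variant_fraction_threshold`` at pooled coverage
    ``>= min_coverage_for_variant_call`` is masked. The mask is therefore
    independent of sample order.
    """
    readsets = list(samples.values()) if isinstance(samples, Mapping) else list(samples)
    if not readsets or all(not rs.windows for rs in readsets):
        warnings.warn("detect_variants: empty read set; returning empty mask")
        return VariantMask.empty(windows)

    win_by_id = {w.gene_id: w for w in windows}
    masked: dict[str, np.ndarray] = {}
    rows = []
    for gene_id, w in win_by_id.items():
        ref = _window_ref(reference, w)
        cov = np.zeros(w.length, dtype=np.int64)
        mis = np.zeros(w.length, dtype=np.int64)
        for rs in readsets:
            wr = rs.windows.get(gene_id)
            if wr is None:
                continue
            covered = wr.matrix != 0
            cov += covered.sum(axis=0)
            mis += (covered & (wr.matrix != ref)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov > 0, mis / np.maximum(cov, 1), 0.0)
        hit = (cov >= config.min_coverage_for_variant_call) & (
            frac >= config.variant_fraction_threshold
        )
        masked[gene_id] = hit
        for off in np.flatnonzero(hit):
            rows.append((w.contig, w.start + int(off), gene_id,
                         int(cov[off]), float(frac[off])))
    fractions = pd.DataFrame(
        rows, columns=["contig", "position", "gene_id", "coverage",
                       "mismatch_fraction"]
    ).sort_values(["contig", "position"], ignore_index=True)
    logger.info("variant mask: %d positions masked", len(fractions))
    return VariantMask(masked, fractions)


# ---------------------------------------------------------------------------
# conversion counting
# ---------------------------------------------------------------------------

def _conversion_layers(
    matrix: np.ndarray, ref: np.ndarray, strand: str, mask_vec: np.ndarray | None
):
    """Shared boolean layers for per-read and per-position accounting."""
    ref_base, alt_base = CONVERSION_BY_STRAND[strand]
    keep = ~mask_vec if mask_vec is not None else np.ones(ref.size, dtype=bool)
    convertible = (ref == ref_base) & keep
    covered = matrix != 0
    mismatch = covered & (matrix != ref) & keep
    tc = mismatch & convertible & (matrix == alt_base)
    return covered, convertible, mismatch, tc


def count_conversions(
    read_seq: str | np.ndarray,
    window: Window,
    reference: Mapping[str, np.ndarray],
    mask: VariantMask | None = None,
    offset: int = 0,
) -> tuple[int, int, int]:
    """Count (convertible T positions, T>C conversions, other mismatches) in one read.

    Strand-aware: a minus-strand gene's conversions appear as reference A read
    as G on the forward strand. Masked positions contribute to none of the
    three counts.
    """
    if isinstance(read_seq, str):
        row = np.frombuffer(read_seq.upper().encode("ascii"), dtype=np.uint8)
    else:
        row = np.asarray(read_seq, dtype=np.uint8)
    if offset < 0 or offset + row.size > window.length:
        raise ValueError(
            f"read does not fit window {window.gene_id} "
            f"(offset {offset}, length {row.size})"
        )
    full = np.zeros(window.length, dtype=np.uint8)
    full[offset : offset + row.size] = row
    ref = _window_ref(reference, window)
    mvec = mask.masked.get(window.gene_id) if mask is not None else None
    covered, convertible, mismatch, tc = _conversion_layers(
        full[None, :], ref, window.strand, mvec
    )
    n_t = int((covered & convertible).sum())
    n_tc = int(tc.sum())
    n_other = int(mismatch.sum()) - n_tc
    return n_t, n_tc, n_other


def classify_read(counts: tuple[int, int, int],
                  config: QuantConfig = QuantConfig()) -> bool:
    """A read is labeled iff it carries >= min_conversions_labeled conversions."""
    return counts[1] >= config.min_conversions_labeled


# ---------------------------------------------------------------------------
# per-window profiles and the count matrix
# ---------------------------------------------------------------------------

@dataclass
class ConversionProfile:
    """Per-window conversion accounting for one sample."""

    gene_id: str
    t_content: int              # convertible positions in the window (strand-aware)
    coverage: np.ndarray        # per-position read coverage
    conversions: np.ndarray     # per-position T>C counts (unmasked positions)
    utr_rate: float             # mean of per-position conversions/coverage; NaN if none
    n_reads: int
    labeled_reads: int
    per_read_conversions: np.ndarray


def quantify_window(
    wr: WindowReads,
    window: Window,
    reference: Mapping[str, np.ndarray],
    mask: VariantMask | None = None,
    config: QuantConfig = QuantConfig(),
) -> ConversionProfile:
    """Vectorised per-window quantification of one sample's reads."""
    ref = _window_ref(reference, window)
    mvec = mask.masked.get(window.gene_id) if mask is not None else None
    covered, convertible, mismatch, tc = _conversion_layers(
        wr.matrix, ref, window.strand, mvec
    )
    per_read_tc = tc.sum(axis=1)
    labeled = int((per_read_tc >= config.min_conversions_labeled).sum())
    cov = covered.sum(axis=0)
    conv = tc.sum(axis=0)
    eligible = convertible & (cov >= config.min_base_coverage_for_rate)
    if eligible.any():
        rate = float(np.mean(conv[eligible] / cov[eligible]))
    else:
        rate = float("nan")
    ref_base, _ = CONVERSION_BY_STRAND[window.strand]
    return ConversionProfile(
        gene_id=window.gene_id,
        t_content=int((ref == ref_base).sum()),
        coverage=cov,
        conversions=conv,
        utr_rate=rate,
        n_reads=wr.matrix.shape[0],
        labeled_reads=labeled,
        per_read_conversions=per_read_tc,
    )


def utr_conversion_rate(
    wr: WindowReads,
    window: Window,
    reference: Mapping[str, np.ndarray],
    mask: VariantMask | None = None,
    config: QuantConfig = QuantConfig(),
) -> float:
    """Mean per-position conversion rate over unmasked, covered T positions.

    Positions below ``min_base_coverage_for_rate`` are excluded; with no
    qualifying position the rate is NaN (missing), never 0.
    """
    return quantify_window(wr, window, reference, mask, config).utr_rate


@dataclass
class LabeledCountMatrix:
    """Genes x samples labeled (>= k conversions) and total read counts."""

    labeled: pd.DataFrame
    total: pd.DataFrame
    samples: pd.DataFrame  # sample_id, arm, time_h, replicate
    utr_rates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.labeled.columns.equals(self.total.columns) or not (
            self.labeled.index.equals(self.total.index)
        ):
            raise ValueError("labeled and total matrices must share axes")
        if (self.labeled.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("labeled_count exceeds total_count")
        missing = set(self.labeled.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.total.sum(axis=0)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wide = pd.concat(
            {"labeled": self.labeled, "total": self.total}, axis=1
        )
        wide.columns = [f"{s}|{kind}" for kind, s in wide.columns]
        wide.sort_index(axis=1).to_csv(outdir / "counts.tsv", sep="\t",
                                       index_label="gene_id")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        if self.utr_rates is not None:
            self.utr_rates.to_csv(outdir / "conversion_rates.tsv", sep="\t",
                                  index_label="gene_id")

    @classmethod
    def read(cls, outdir: str | Path) -> "LabeledCountMatrix":
        outdir = Path(outdir)
        wide = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="gene_id")
        labeled = wide[[c for c in wide.columns if c.endswith("|labeled")]].copy()
        labeled.columns = [c.rsplit("|", 1)[0] for c in labeled.columns]
        total = wide[[c for c in wide.columns if c.endswith("|total")]].copy()
        total.columns = [c.rsplit("|", 1)[0] for c in total.columns]
        samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
        order = [s for s in samples["sample_id"] if s in labeled.columns]
        rates_path = outdir / "conversion_rates.tsv"
        rates = (pd.read_csv(rates_path, sep="\t", index_col="gene_id")
                 if rates_path.exists() else None)
        return cls(labeled[order], total[order], samples, rates)


def build_count_matrix(
    samples: Mapping[str, AlignedReadSet],
    sample_sheet: pd.DataFrame,
    windows: Sequence[Window],
    reference: Mapping[str, np.ndarray],
    mask: VariantMask | None = None,
    config: QuantConfig = QuantConfig(),
) -> LabeledCountMatrix:
    """Quantify every sample against a shared mask into a count matrix.

    Gene and sample ordering is deterministic: genes in window order, samples
    in sample-sheet order. Raises if the sheet names samples that were not
    provided.
    """
    sheet_ids = list(sample_sheet["sample_id"])
    missing = [s for s in sheet_ids if s not in samples]
    if missing:
        raise ValueError(f"sample sheet lists samples with no reads: {missing}")
    gene_ids = [w.gene_id for w in windows]
    win_by_id = {w.gene_id: w for w in windows}
    labeled = pd.DataFrame(0, index=gene_ids, columns=sheet_ids, dtype=np.int64)
    total = pd.DataFrame(0, index=gene_ids, columns=sheet_ids, dtype=np.int64)
    rates = pd.DataFrame(np.nan, index=gene_ids, columns=sheet_ids, dtype=float)
    for sid in sheet_ids:
        rs = samples[sid]
        for gene_id, wr in rs.windows.items():
            prof = quantify_window(wr, win_by_id[gene_id], reference, mask, config)
            labeled.loc[gene_id, sid] = prof.labeled_reads
            total.loc[gene_id, sid] = prof.n_reads
            rates.loc[gene_id, sid] = prof.utr_rate
    labeled.index.name = total.index.name = rates.index.name = "gene_id"
    return LabeledCountMatrix(labeled, total, sample_sheet.copy(), rates)
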