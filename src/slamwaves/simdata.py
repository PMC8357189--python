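"""Synthetic inducible-SLAM-seq study generator.

Emulates a rapid TF-induction experiment: a TF fused to an ERT2 domain is
activated at t=0, cells are pulse-labeled with s4U for 15 minutes before each
harvest, and 3'-anchored counting windows are sequenced at 0, 0.5, 1, 2, 4 and
8 h in an induced and a control arm (2 replicates each). Nascent transcripts
carry T>C conversions at ~2.5% per T over a ~0.1% background.

Planted gene classes drive step-function transcription-rate profiles:

* ``IE_transient``   — bound by the TF; rate shifts at 0.5-1 h, reverts by 2 h
* ``IE_sustained``   — bound; rate shifts at 0.5-1 h and stays shifted
* ``delayed``        — bound; rate first shifts at >= 2 h and stays shifted
* ``secondary``      — unbound; rate first shifts at >= 2 h (via intermediary)
* ``unresponsive``   — flat in both arms

The control arm is flat for every gene. Occupancy peaks are planted for bound
genes, promoter-biased (default 61.2% of peaks in the promoter window), with a
configurable detection rate emulating assay sensitivity.

All outputs are deterministic functions of (config, seed); per-sample RNG
streams are derived by stable hashing of the sample name so samples can be
regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .slamquant import (
    CONVERSION_BY_STRAND,
    AlignedReadSet,
    Window,
    WindowReads,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_CLASSES = ("IE_transient", "IE_sustained", "delayed", "secondary",
                "unresponsive")
RESPONSIVE_CLASSES = GENE_CLASSES[:4]
BOUND_CLASSES = ("IE_transient", "IE_sustained", "delayed")
ARMS = ("induced", "control")

DEFAULT_CLASS_MIX = {
    "IE_transient": 0.10,
    "IE_sustained": 0.10,
    "delayed": 0.15,
    "secondary": 0.15,
    "unresponsive": 0.50,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and chemistry parameters of the simulated experiment.

    The defaults are the simulated study's conditions: 6 harvests at
    (0, 0.5, 1, 2, 4, 8) h x 2 arms x 2 replicates, 2.5% T>C conversion per T
    position in labeled reads over a 0.1% background, an 80% baseline labeled
    fraction in the 3' windows (which places the bulk per-T conversion rate
    near 2%, inside the 1.5-3.5% band such pulses produce), and a 61.2%
    promoter bias for planted occupancy peaks.
    """

    n_genes: int = 200
    window_length: int = 250
    gene_length: int = 2000
    intergenic_length: int = 5000
    genes_per_contig: int = 25
    time_points_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_replicates: int = 2
    p_conv: float = 0.025
    p_err: float = 0.001
    snp_fraction: float = 0.1
    mean_depth: float = 100.0
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    effect_size_log2: float = 1.0
    prob_up: float = 0.5
    base_labeled_fraction: float = 0.8
    promoter_peak_fraction: float = 0.612
    promoter_upstream_bp: int = 2000
    promoter_downstream_bp: int = 500
    peak_width: int = 400
    peak_detection_rate: float = 1.0
    n_decoy_peaks: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.window_length < 50:
            raise ValueError(
                "window_length < 50 refused: too few convertible positions for "
                "the >=2-conversion labeled-read rule to be meaningful")
        if self.gene_length < self.window_length:
            raise ValueError("gene_length must be >= window_length")
        tp = tuple(float(t) for t in self.time_points_h)
        if tp[0] != 0.0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points_h must be strictly increasing from 0")
        object.__setattr__(self, "time_points_h", tp)
        if not (0.0 <= self.p_err < self.p_conv <= 1.0):
            raise ValueError("require 0 <= p_err < p_conv <= 1")
        mix = {k: float(v) for k, v in self.class_mix.items()}
        unknown = set(mix) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes in class_mix: {sorted(unknown)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        object.__setattr__(self, "class_mix", mix)
        if not (0.0 <= self.base_labeled_fraction <= 1.0):
            raise ValueError("base_labeled_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(build_sample_sheet(self)["sample_id"])


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Derive a named child stream from the master seed (stable across runs)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def build_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{arm}_{t:g}h_r{rep}", "arm": arm, "time_h": t,
         "replicate": rep}
        for arm in ARMS
        for t in config.time_points_h
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference and gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One simulated gene: locus, counting window, planted class and binding."""

    gene_id: str
    contig: str
    start: int          # gene span, 0-based half-open
    end: int
    strand: str
    tss: int
    window_start: int   # 3'-anchored counting window
    window_end: int
    true_class: str
    direction: str | None   # up/down for responsive classes, else None
    bound: bool
    t_count: int            # convertible positions in the window

    def __post_init__(self) -> None:
        if self.end - self.start < 1 or self.window_end <= self.window_start:
            raise ValueError(f"{self.gene_id}: degenerate interval")
        if self.t_count > self.window_end - self.window_start:
            raise ValueError(f"{self.gene_id}: t_count exceeds window length")
        if self.true_class in BOUND_CLASSES and not self.bound:
            raise ValueError(f"{self.gene_id}: direct-target classes must be bound")
        if self.true_class == "secondary" and self.bound:
            raise ValueError(f"{self.gene_id}: secondary genes must be unbound")

    @property
    def window(self) -> Window:
        return Window(self.gene_id, self.contig, self.window_start,
                      self.window_end, self.strand)


@dataclass
class Reference:
    """Simulated genome: contig sequences plus gene models."""

    contigs: dict[str, np.ndarray]
    genes: list[GeneModel]

    @property
    def windows(self) -> list[Window]:
        return [g.window for g in self.genes]


def _apportion(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the class mix."""
    keys = [k for k in GENE_CLASSES if k in mix]
    raw = np.array([mix[k] * n for k in keys])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(keys, counts))


def build_reference(config: SimConfig) -> Reference:
    """Lay out genes on chromosome-like contigs and draw their sequences.

    Each contig carries ``genes_per_contig`` loci separated by
    ``intergenic_length`` of flank, plus a long gene-free tail where decoy
    peaks can be placed. Counting windows are the 3'-terminal
    ``window_length`` bases of each gene (strand-aware).
    """
    rng = child_rng(config.seed, "reference")
    counts = _apportion(config.class_mix, config.n_genes)
    class_labels = np.repeat(
        [k for k in counts], [counts[k] for k in counts])
    class_labels = class_labels[rng.permutation(config.n_genes)]
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    directions = np.where(rng.random(config.n_genes) < config.prob_up,
                          "up", "down")

    pitch = config.gene_length + config.intergenic_length
    tail = 30_000
    n_contigs = -(-config.n_genes // config.genes_per_contig)
    contigs: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    for ci in range(n_contigs):
        lo = ci * config.genes_per_contig
        hi = min(lo + config.genes_per_contig, config.n_genes)
        n_here = hi - lo
        contig = f"chr{ci + 1}"
        length = config.intergenic_length + n_here * pitch + tail
        seq = _BASES[rng.integers(0, 4, size=length)]
        contigs[contig] = seq
        for j in range(n_here):
            idx = lo + j
            gstart = config.intergenic_length + j * pitch
            gend = gstart + config.gene_length
            strand = str(strands[idx])
            if strand == "+":
                tss = gstart
                wstart, wend = gend - config.window_length, gend
            else:
                tss = gend - 1
                wstart, wend = gstart, gstart + config.window_length
            cls = str(class_labels[idx])
            ref_base, _ = CONVERSION_BY_STRAND[strand]
            t_count = int((seq[wstart:wend] == ref_base).sum())
            genes.append(GeneModel(
                gene_id=f"gene{idx:05d}",
                contig=contig, start=gstart, end=gend, strand=strand, tss=tss,
                window_start=wstart, window_end=wend,
                true_class=cls,
                direction=str(directions[idx]) if cls != "unresponsive" else None,
                bound=cls in BOUND_CLASSES,
                t_count=t_count,
            ))
    return Reference(contigs, genes)


# ---------------------------------------------------------------------------
# kinetics and ground truth
# ---------------------------------------------------------------------------

def kinetic_profile(true_class: str, times: Sequence[float], effect_log2: float,
                    direction: str | None, onset_h: float) -> np.ndarray:
    """Relative transcription rate (vs 0 h) at each time point, as a step function.

    The fold change is ``2**effect_log2`` (up) or ``2**-effect_log2`` (down).
    IE classes shift at ``onset_h`` in {0.5, 1}; the transient subclass reverts
    to baseline at every t >= 2 h, the sustained subclass stays shifted.
    Delayed and secondary classes first shift at ``onset_h`` >= 2 h and stay
    shifted through the last harvest.
    """
    times = np.asarray(times, dtype=float)
    ratio = np.ones_like(times)
    if true_class == "unresponsive":
        return ratio
    r = 2.0 ** (effect_log2 if direction == "up" else -effect_log2)
    if true_class == "IE_transient":
        ratio[(times >= onset_h) & (times < 2.0)] = r
    elif true_class in ("IE_sustained", "delayed", "secondary"):
        ratio[times >= onset_h] = r
    else:
        raise ValueError(f"unknown gene class {true_class!r}")
    return ratio


@dataclass(eq=False)
class SimTruth:
    """Planted ground truth: gene models, kinetic profiles, SNP positions."""

    config: SimConfig
    genes: list[GeneModel]
    onsets_h: np.ndarray            # per gene; 0 for unresponsive
    abundance: np.ndarray           # genes x time points, induced arm, vs-0h ratio
    snp_positions: set[tuple[str, int]]
    reference: Reference | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimTruth):
            return NotImplemented
        return (self.config == other.config
                and self.genes == other.genes
                and np.array_equal(self.onsets_h, other.onsets_h)
                and np.array_equal(self.abundance, other.abundance)
                and self.snp_positions == other.snp_positions)

    def abundance_for(self, arm: str) -> np.ndarray:
        """Expected relative labeled-transcript level per gene x time point."""
        if arm == "induced":
            return self.abundance
        if arm == "control":
            return np.ones_like(self.abundance)
        raise KeyError(f"unknown arm {arm!r}")

    @property
    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.genes])


def simulate_timecourse(config: SimConfig) -> SimTruth:
    """Build the reference and plant per-gene kinetic profiles and SNPs."""
    reference = build_reference(config)
    rng = child_rng(config.seed, "kinetics")
    times = np.asarray(config.time_points_h)
    ie_choices = [t for t in config.time_points_h if 0.0 < t < 2.0] or [times[1]]
    late_choices = [t for t in config.time_points_h if t >= 2.0]
    needs_late = any(config.class_mix.get(c, 0) > 0
                     for c in ("delayed", "secondary"))
    if needs_late and not late_choices:
        raise ValueError(
            "delayed/secondary classes need at least one harvest at >= 2 h")
    onsets = np.zeros(len(reference.genes))
    abundance = np.ones((len(reference.genes), times.size))
    for i, g in enumerate(reference.genes):
        if g.true_class == "unresponsive":
            continue
        pool = ie_choices if g.true_class.startswith("IE") else late_choices
        onsets[i] = pool[rng.integers(len(pool))]
        abundance[i] = kinetic_profile(
            g.true_class, times, config.effect_size_log2, g.direction, onsets[i])

    snp_rng = child_rng(config.seed, "snps")
    n_snp = int(round(config.snp_fraction * config.n_genes))
    snp_positions: set[tuple[str, int]] = set()
    if n_snp:
        chosen = snp_rng.choice(len(reference.genes), size=n_snp, replace=False)
        for i in sorted(chosen):
            g = reference.genes[i]
            seq = reference.contigs[g.contig][g.window_start:g.window_end]
            ref_base, _ = CONVERSION_BY_STRAND[g.strand]
            t_offsets = np.flatnonzero(seq == ref_base)
            if t_offsets.size == 0:
                continue
            off = int(t_offsets[snp_rng.integers(t_offsets.size)])
            snp_positions.add((g.contig, g.window_start + off))
    return SimTruth(config, reference.genes, onsets, abundance, snp_positions,
                    reference)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _labeled_fraction(ratio: float, f0: float) -> float:
    """Labeled fraction of the window's reads at relative transcription rate.

    The pre-existing (unlabeled) pool is steady over the 15-min pulse while
    the nascent (labeled) pool scales with the transcription rate, so the
    labeled fraction is f0*r / ((1-f0) + f0*r) and total abundance scales as
    (1-f0) + f0*r.
    """
    rel_total = (1.0 - f0) + f0 * ratio
    if rel_total == 0.0:
        return 0.0
    return f0 * ratio / rel_total


def simulate_sample_reads(truth: SimTruth, sample_id: str) -> AlignedReadSet:
    """Draw one sample's aligned reads from the planted truth.

    Per window: read count ~ Poisson(mean_depth x relative total abundance);
    each read is labeled with the time course's labeled fraction; labeled reads
    gain T>C conversions at unmasked convertible positions with ``p_conv``;
    every read gains background substitutions at ``p_err`` (uniform over the 3
    alternative bases); planted SNP positions are altered in every read.
    """
    config = truth.config
    sheet = build_sample_sheet(config)
    row = sheet[sheet["sample_id"] == sample_id]
    if row.empty:
        raise KeyError(f"sample {sample_id!r} is not part of this design")
    arm = row["arm"].item()
    t_idx = config.time_points_h.index(float(row["time_h"].item()))
    rng = child_rng(config.seed, f"reads:{sample_id}")
    f0 = config.base_labeled_fraction
    ratios = truth.abundance_for(arm)[:, t_idx]
    reference = truth.reference if truth.reference is not None else \
        build_reference(config)

    windows_out: dict[str, WindowReads] = {}
    for gi, g in enumerate(truth.genes):
        ratio = float(ratios[gi])
        rel_total = (1.0 - f0) + f0 * ratio
        n = int(rng.poisson(config.mean_depth * rel_total))
        if n == 0:
            continue
        ref = reference.contigs[g.contig][g.window_start:g.window_end]
        mat = np.tile(ref, (n, 1))
        ref_base, alt_base = CONVERSION_BY_STRAND[g.strand]
        snp_cols = np.array(
            [pos - g.window_start for (c, pos) in truth.snp_positions
             if c == g.contig and g.window_start <= pos < g.window_end],
            dtype=int)
        if snp_cols.size:
            # planted homozygous-like variant: reads as the conversion base
            mat[:, snp_cols] = alt_base
        labeled = rng.random(n) < _labeled_fraction(ratio, f0)
        convertible = (ref == ref_base)
        if snp_cols.size:
            convertible = convertible.copy()
            convertible[snp_cols] = False
        if labeled.any() and config.p_conv > 0:
            conv_hits = (rng.random((n, ref.size)) < config.p_conv)
            conv_hits &= labeled[:, None] & convertible[None, :]
            mat[conv_hits] = alt_base
        else:
            conv_hits = np.zeros((n, ref.size), dtype=bool)
        if config.p_err > 0:
            err_hits = rng.random((n, ref.size)) < config.p_err
            err_hits &= ~conv_hits
            if snp_cols.size:
                err_hits[:, snp_cols] = False
            idx = np.nonzero(err_hits)
            if idx[0].size:
                # uniform among the 3 non-reference bases
                ref_rank = np.searchsorted(_BASES, ref[idx[1]])
                alt_rank = (ref_rank + 1 + rng.integers(0, 3, idx[0].size)) % 4
                mat[idx] = _BASES[alt_rank]
        read_ids = [f"{sample_id}:{g.gene_id}:{k}" for k in range(n)]
        windows_out[g.gene_id] = WindowReads(read_ids, mat)
    return AlignedReadSet(sample_id, windows_out)


def simulate_reads(truth: SimTruth,
                   sample_ids: Sequence[str] | None = None
                   ) -> dict[str, AlignedReadSet]:
    """Simulate all samples of the design (or the requested subset)."""
    ids = sample_ids or truth.config.sample_ids
    return {sid: simulate_sample_reads(truth, sid) for sid in ids}


# ---------------------------------------------------------------------------
# occupancy simulation
# ---------------------------------------------------------------------------

def simulate_occupancy(truth: SimTruth) -> pd.DataFrame:
    """Plant occupancy peaks for bound genes (plus optional intergenic decoys).

    Each bound gene yields one peak with probability ``peak_detection_rate``;
    with probability ``promoter_peak_fraction`` the peak midpoint falls in the
    gene's strand-aware promoter window, otherwise in the gene body downstream
    of it. Unbound genes never receive a peak. Decoy peaks land in the gene-free
    contig tails, farther from every TSS than any sensible assignment cutoff.
    """
    config = truth.config
    rng = child_rng(config.seed, "occupancy")
    up, down = config.promoter_upstream_bp, config.promoter_downstream_bp
    half = config.peak_width // 2
    rows = []
    for g in truth.genes:
        if not g.bound or rng.random() >= config.peak_detection_rate:
            continue
        in_promoter = rng.random() < config.promoter_peak_fraction
        if in_promoter:
            signed = int(rng.integers(-up, down + 1))
        else:
            body_lo = down + 100
            body_hi = (g.end - g.start) - 1
            signed = int(rng.integers(body_lo, body_hi + 1))
        mid = g.tss + signed if g.strand == "+" else g.tss - signed
        rows.append({
            "peak_id": "", "contig": g.contig,
            "start": max(0, mid - half), "end": mid + half,
            "score": float(rng.integers(50, 500)),
            "planted_gene": g.gene_id,
            "planted_feature": "promoter" if in_promoter else "gene_body",
        })
    if config.n_decoy_peaks and truth.reference is not None:
        contig_names = list(truth.reference.contigs)
        for _ in range(config.n_decoy_peaks):
            contig = contig_names[rng.integers(len(contig_names))]
            clen = truth.reference.contigs[contig].size
            last_tss = max((g.tss for g in truth.genes if g.contig == contig),
                           default=0)
            lo = max(last_tss + 12_000, clen - 30_000 + 2_000)
            mid = int(rng.integers(lo, clen - half))
            rows.append({"peak_id": "", "contig": contig,
                         "start": mid - half, "end": mid + half,
                         "score": float(rng.integers(50, 500)),
                         "planted_gene": None, "planted_feature": "decoy"})
    peaks = pd.DataFrame(
        rows, columns=["peak_id", "contig", "start", "end", "score",
                       "planted_gene", "planted_feature"])
    peaks = peaks.sort_values(["contig", "start"], ignore_index=True)
    peaks["peak_id"] = [f"peak{i:05d}" for i in range(len(peaks))]
    return peaks


# ---------------------------------------------------------------------------
# writers / readers (plain-text formats)
# ---------------------------------------------------------------------------

def write_fasta(reference: Reference, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in reference.contigs:
            fh.write(f">{name}\n")
            seq = reference.contigs[name].tobytes().decode("ascii")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    """Load a FASTA into contig -> uint8 byte arrays (via pyfaidx)."""
    from pyfaidx import Fasta

    out = {}
    with Fasta(str(path), as_raw=True) as fa:
        for name in fa.keys():
            out[name] = np.frombuffer(
                str(fa[name][:]).upper().encode("ascii"), dtype=np.uint8)
    return out


def write_windows_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.window_start}\t{g.window_end}\t"
                     f"{g.gene_id}\t0\t{g.strand}\n")


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Gene spans as BED6 (TSS is the strand-dependent 5' end)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\n")


def read_bed_windows(path: str | Path) -> list[Window]:
    wins = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            wins.append(Window(f[3], f[0], int(f[1]), int(f[2]),
                               f[5] if len(f) > 5 else "+"))
    return wins


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in peaks.itertuples(index=False):
            score = int(r.score) if "score" in peaks.columns else 0
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.peak_id}\t{score}\t.\n")


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({"peak_id": f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                         "contig": f[0], "start": int(f[1]), "end": int(f[2]),
                         "score": float(f[4]) if len(f) > 4 else 0.0})
    return pd.DataFrame(rows)


def write_sam(reads: AlignedReadSet, reference: Reference,
              path: str | Path) -> None:
    """Write a coordinate-sorted plain-text SAM file (via pysam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(seq.size)}
               for name, seq in reference.contigs.items()],
    }
    gene_by_id = {g.gene_id: g for g in reference.genes}
    order = sorted(reads.windows,
                   key=lambda gid: (gene_by_id[gid].contig,
                                    gene_by_id[gid].window_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for gid in order:
            g = gene_by_id[gid]
            wr = reads.windows[gid]
            tid = sam.get_tid(g.contig)
            for i, rid in enumerate(wr.read_ids):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = rid
                a.query_sequence = wr.matrix[i].tobytes().decode("ascii")
                a.flag = 0
                a.reference_id = tid
                a.reference_start = g.window_start
                a.mapping_quality = 255
                a.cigarstring = f"{wr.matrix.shape[1]}M"
                sam.write(a)


def write_reads_tsv(reads: AlignedReadSet, reference: Reference,
                    path: str | Path) -> None:
    """Write the tabular read dialect: read_id, contig, start, strand, sequence."""
    gene_by_id = {g.gene_id: g for g in reference.genes}
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstart\tstrand\tsequence\n")
        for gid in sorted(reads.windows,
                          key=lambda gid: (gene_by_id[gid].contig,
                                           gene_by_id[gid].window_start)):
            g = gene_by_id[gid]
            wr = reads.windows[gid]
            for i, rid in enumerate(wr.read_ids):
                seq = wr.matrix[i].tobytes().decode("ascii")
                fh.write(f"{rid}\t{g.contig}\t{g.window_start}\t{g.strand}\t"
                         f"{seq}\n")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "config": {**dataclasses.asdict(truth.config),
                   "time_points_h": list(truth.config.time_points_h)},
        "genes": [dataclasses.asdict(g) for g in truth.genes],
        "onsets_h": truth.onsets_h.tolist(),
        "abundance": truth.abundance.tolist(),
        "snp_positions": sorted([c, int(p)] for c, p in truth.snp_positions),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path, rebuild_reference: bool = False) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    cfg["time_points_h"] = tuple(cfg["time_points_h"])
    config = SimConfig(**cfg)
    genes = [GeneModel(**g) for g in payload["genes"]]
    truth = SimTruth(
        config, genes,
        np.asarray(payload["onsets_h"], dtype=float),
        np.asarray(payload["abundance"], dtype=float),
        {(c, int(p)) for c, p in payload["snp_positions"]},
        build_reference(config) if rebuild_reference else None,
    )
    return truth


def write_study(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the full simulated study (reference, annotations, reads, peaks).

    Returns the paths written. Reads go out in both SAM and the TSV dialect.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = truth.reference or build_reference(truth.config)
    paths = {
        "reference": outdir / "reference.fa",
        "windows": outdir / "windows.bed",
        "genes": outdir / "genes.bed",
        "peaks": outdir / "peaks.bed",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(reference, paths["reference"])
    write_windows_bed(truth.genes, paths["windows"])
    write_genes_bed(truth.genes, paths["genes"])
    write_peaks_bed(simulate_occupancy(truth), paths["peaks"])
    sheet = build_sample_sheet(truth.config)
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    write_truth(truth, paths["truth"])
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    counts = []
    for sid in sheet["sample_id"]:
        rs = simulate_sample_reads(truth, sid)
        write_sam(rs, reference, reads_dir / f"{sid}.sam")
        write_reads_tsv(rs, reference, reads_dir / f"{sid}.tsv")
        counts.append({"sample_id": sid, "n_reads": rs.n_reads})
    pd.DataFrame(counts).to_csv(outdir / "read_counts.tsv", sep="\t",
                                index=False)
    paths["reads"] = reads_dir
    return paths
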