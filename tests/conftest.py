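import numpy as np
import pytest

import slamwaves as sw


@pytest.fixture(scope="session")
def study_config() -> sw.SimConfig:
    """A small but fully featured study reused across module tests."""
    return sw.SimConfig(
        n_genes=40,
        window_length=150,
        gene_length=1200,
        mean_depth=120,
        snp_fraction=0.15,
        class_mix={c: 0.2 for c in sw.GENE_CLASSES},
        seed=11,
    )


@pytest.fixture(scope="session")
def study(study_config):
    """Simulated truth + reads + pooled variant mask + count matrix."""
    truth = sw.simulate_timecourse(study_config)
    reads = sw.simulate_reads(truth)
    windows = truth.reference.windows
    mask = sw.detect_variants(reads, truth.reference.contigs, windows)
    sheet = sw.build_sample_sheet(study_config)
    counts = sw.build_count_matrix(reads, sheet, windows,
                                   truth.reference.contigs, mask)
    return {"truth": truth, "reads": reads, "windows": windows,
            "mask": mask, "counts": counts, "sheet": sheet}


def make_window(gene_id="g1", contig="chr1", start=0, length=60, strand="+"):
    return sw.Window(gene_id, contig, start, start + length, strand)


def manual_reference(seq: str, contig="chr1"):
    return {contig: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)}
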