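import pathlib

import numpy as np
import pytest

import rindseq as rs
from rindseq.linker import read_sequences


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def plant_genome(cores_with_context, seed=7, spacer=60):
    """Concatenate (context, core) pairs separated by random spacers;
    returns the genome and the core start positions."""
    rng = np.random.default_rng(seed)
    parts, positions, cursor = [], [], 0
    for ctx, core in cores_with_context:
        sp = "".join("ACGT"[b] for b in rng.integers(0, 4, spacer))
        parts.append(sp + ctx)
        cursor += len(sp) + len(ctx)
        positions.append(cursor)
        parts.append(core)
        cursor += len(core)
    parts.append("".join("ACGT"[b] for b in rng.integers(0, 4, spacer)))
    return rs.ReferenceGenome({"chr1": "".join(parts)}), positions


def observable_truths(genome, truths, min_align_length=20):
    """Truth records the capture protocol can actually report: intact
    first linker and a mappable fragment (the RsaI cut must leave at least
    min_align_length bases after half-site trimming)."""
    out = []
    for t in truths:
        if not t.linker_intact:
            continue
        frag, _ = rs.capture_fragment(genome[t.chrom], t.break_pos, t.strand)
        if len(frag) - 2 >= min_align_length:
            out.append(t)
    return out

# Published contingency counts for the ten yeast samples (wild type,
# caffeine-treated, day-50 aged, and seven repair-deletion mutants).
# Repair-defect association rows: (MIB + OR<=1 breaks, OR>1 breaks) in the
# sample vs the same counts in wild type, with the published p-value and OR.
REPAIR_DEFECT_ROWS = {
    "wt_caffeine": (879, 557, 750, 1012, 7.29e-26, 2.13),
    "wt_day50": (2816, 1728, 750, 1012, 5.43e-44, 2.20),
    "mec1": (1939, 114, 750, 1012, 6.66e-294, 22.93),
    "mre11": (1855, 234, 750, 1012, 1.02e-214, 10.69),
    "nej1": (2742, 2049, 750, 1012, 6.30e-26, 1.81),
    "rad51": (1763, 191, 750, 1012, 1.32e-224, 12.45),
    "tel1": (3179, 368, 750, 1012, 5.44e-288, 11.65),
    "yku70": (2589, 290, 750, 1012, 7.27e-268, 12.04),
    "yku80": (1039, 82, 750, 1012, 1.95e-183, 17.08),
}

# MIB-association rows: (OR<=1, OR>1) among reads not mapped from the first
# base vs the same split among reads mapped from the first base.
MIB_ASSOCIATION_ROWS = {
    "wild_type": (164, 94, 492, 1012, 1.82e-20, 3.59),
    "wt_caffeine": (92, 87, 700, 557, 2.97e-01, 0.84),
    "wt_day50": (518, 424, 1874, 1728, 1.07e-01, 1.13),
    "mec1": (846, 949, 144, 114, 9.38e-03, 0.71),
    "mre11": (669, 932, 254, 234, 7.45e-05, 0.66),
    "nej1": (548, 387, 1807, 2049, 1.26e-10, 1.61),
    "rad51": (587, 933, 243, 191, 1.43e-10, 0.49),
    "tel1": (1009, 1757, 413, 368, 2.83e-16, 0.51),
    "yku70": (1093, 1145, 351, 290, 9.34e-03, 0.79),
    "yku80": (429, 555, 55, 82, 4.63e-01, 1.15),
}

# Repair-defect rows where the published OR differs from the cross-product
# at 2 dp (conditional-MLE output of the exact-test software). The three
# most unbalanced tables (largest discrepancy) plus two rows that differ
# only in the final rounded digit.
CMLE_ONLY_ROWS = {
    "mec1": 22.93,
    "tel1": 11.65,
    "yku80": 17.08,
    "mre11": 10.69,
    "yku70": 12.04,
}
CMLE_LARGE_GAP_ROWS = {"mec1": 22.93, "tel1": 11.65, "yku80": 17.08}

ENRICHED_4MERS = {"ACGT": 50.0, "TTAA": 50.0}


def pipeline_on_library(genome, truths, config, workdir, params=None):
    """Run linker-processing + mapping over a simulated library."""
    workdir = pathlib.Path(workdir)
    lk = rs.LinkerConfig(
        config.linker_first,
        unique3_length=len(config.linker_first_unique),
        second_linker=config.linker_second,
    )
    reads = list(read_sequences(workdir / "reads.fastq"))
    retained, flog = rs.process_reads(reads, lk)
    calls, mlog = rs.map_reads(retained, genome, params or rs.MappingParams())
    return retained, flog, calls, mlog


@pytest.fixture(scope="session")
def enriched_library(tmp_path_factory):
    """50 kb genome, 5000 error-free reads, two strongly enriched break
    4-mers, 30% MIB with 3-8 bp inserts — the parameter-recovery study."""
    cfg = rs.SimulationConfig(
        genome_length=50_000,
        n_chromosomes=1,
        gc_fraction=0.38,
        n_reads=5000,
        enriched_4mers=dict(ENRICHED_4MERS),
        mib_rate=0.3,
        insert_length_range=(3, 8),
        corrupt_linker_rate=0.1,
        error_rate=0.0,
        seed=1,
    )
    outdir = tmp_path_factory.mktemp("enriched_library")
    genome, truths = rs.simulate_library(cfg, outdir)
    return {"config": cfg, "genome": genome, "truths": truths, "dir": outdir}


@pytest.fixture(scope="session")
def enriched_calls(enriched_library):
    """Break calls from the full pipeline over the enriched library."""
    lib = enriched_library
    retained, flog, calls, mlog = pipeline_on_library(
        lib["genome"], lib["truths"], lib["config"], lib["dir"]
    )
    return {"retained": retained, "flog": flog, "calls": calls, "mlog": mlog, **lib}


@pytest.fixture(scope="session")
def small_library(tmp_path_factory):
    """10 kb genome, 600 reads: a quick unbiased library."""
    cfg = rs.SimulationConfig(
        genome_length=10_000,
        n_reads=600,
        mib_rate=0.15,
        insert_length_range=(3, 8),
        corrupt_linker_rate=0.25,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("small_library")
    genome, truths = rs.simulate_library(cfg, outdir)
    return {"config": cfg, "genome": genome, "truths": truths, "dir": outdir}
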