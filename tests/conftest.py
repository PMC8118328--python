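import numpy as np
import pytest

import editome as ed
from editome import sim


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A compact simulated study shared across tests: one WT sample.

    Two chromosomes, ~60 planted sites, depth 50, default error rate.
    """
    outdir = tmp_path_factory.mktemp("small_study")
    genome, models = ed.simulate_genome(2, 20000, seed=7)
    truth = ed.plant_truth_sites(genome, models, 60, seed=1)
    sam = str(outdir / "wt.sam")
    n_reads = ed.simulate_reads(
        genome, models, truth, ed.WT, sam, depth=50, seed=5
    )
    return {
        "dir": outdir,
        "genome": genome,
        "models": models,
        "truth": truth,
        "sam": sam,
        "n_reads": n_reads,
    }


@pytest.fixture(scope="session")
def wt_reads(small_study):
    reads, ref_lengths = ed.read_sam(small_study["sam"])
    ed.mark_duplicates(reads)
    return reads, ref_lengths


def brute_force_pileup(reads, chrom, start, end, min_bq=20, min_mq=20):
    """Independent O(reads x length) pileup oracle.

    Walks each read base by base with explicit CIGAR semantics and applies
    the same floors and mate-overlap rule (higher quality wins, ties keep
    the earlier read in input order) as the pileup under test.
    """
    per_pos = {}  # pos -> {name: (base, qual, is_reverse)}
    for r in reads:
        if r.chrom != chrom or r.is_duplicate or r.mapq < min_mq:
            continue
        rpos = r.pos
        qpos = 0
        for op, length in r.cigar:
            if op in (0, 7, 8):  # M, =, X
                for i in range(length):
                    p = rpos + i
                    if start <= p <= end:
                        q = r.quals[qpos + i]
                        b = r.seq[qpos + i]
                        if q >= min_bq and b != "N":
                            slot = per_pos.setdefault(p, {})
                            old = slot.get(r.name)
                            if old is None or q > old[1]:
                                slot[r.name] = (b, q, r.is_reverse)
                rpos += length
                qpos += length
            elif op in (1, 4):  # I, S
                qpos += length
            elif op in (2, 3):  # D, N
                rpos += length
    out = {}
    for p, slot in per_pos.items():
        counts = {}
        for b, q, rev in slot.values():
            counts.setdefault(b, [0, 0, []])
            if rev:
                counts[b][1] += 1
            else:
                counts[b][0] += 1
            counts[b][2].append(q)
        out[p] = {b: (v[0], v[1], sorted(v[2])) for b, v in counts.items()}
    return out
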