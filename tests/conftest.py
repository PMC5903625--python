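"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtxprof.orfs import Orf, OrfCatalog
from mtxprof.quantify import AlignmentRecord


@pytest.fixture
def tiny_catalog() -> OrfCatalog:
    """Two contigs, three ORFs; c1 carries two abutting ORFs."""
    return OrfCatalog(
        [
            Orf("orfA", "c1", 100, 400),
            Orf("orfB", "c1", 400, 700),
            Orf("orfC", "c2", 50, 350, strand="-"),
        ]
    )


def make_record(contig, start, length, sample="s1", read_id="r1"):
    return AlignmentRecord(
        read_id=read_id,
        contig_id=contig,
        start=start,
        aligned_blocks=((start, start + length),),
        sample_id=sample,
    )


def per_base_count_oracle(records, catalog) -> pd.DataFrame:
    """Brute-force aligned-nucleotide counting: one pass per base position."""
    samples = sorted({r.sample_id for r in records})
    out = pd.DataFrame(
        0, index=pd.Index(catalog.orf_ids, name="orf_id"), columns=samples, dtype=np.int64
    )
    for rec in records:
        for orf in catalog.on_contig(rec.contig_id):
            bases = 0
            for bs, be in rec.aligned_blocks:
                for pos in range(bs, be):
                    if orf.start <= pos < orf.end:
                        bases += 1
            if bases:
                out.loc[orf.orf_id, rec.sample_id] += bases
    return out


def random_counting_instance(rng, max_contig=1000, max_reads=20):
    """A random small counting instance: contigs ≤ 1 kb, ≤ 20 reads."""
    n_contigs = int(rng.integers(1, 4))
    orfs, contig_lens = [], {}
    oid = 0
    for ci in range(n_contigs):
        cid = f"c{ci}"
        clen = int(rng.integers(200, max_contig + 1))
        contig_lens[cid] = clen
        pos = 0
        while pos < clen - 30 and rng.random() < 0.8:
            start = int(rng.integers(pos, clen - 20))
            end = int(rng.integers(start + 10, min(clen, start + 400) + 1))
            orfs.append(Orf(f"o{oid}", cid, start, end))
            oid += 1
            pos = end  # abutting or gapped, never overlapping
    if not orfs:
        orfs.append(Orf("o0", "c0", 10, 100))
    catalog = OrfCatalog(orfs)
    records = []
    n_reads = int(rng.integers(0, max_reads + 1))
    for ri in range(n_reads):
        cid = f"c{int(rng.integers(0, n_contigs))}"
        clen = contig_lens.get(cid, 200)
        start = int(rng.integers(0, max(1, clen - 30)))
        # occasionally a two-block (spliced/indel-split) alignment
        if rng.random() < 0.3 and start + 60 < clen:
            l1 = int(rng.integers(5, 25))
            gap = int(rng.integers(1, 10))
            l2 = int(rng.integers(5, min(25, clen - start - l1 - gap)))
            blocks = ((start, start + l1), (start + l1 + gap, start + l1 + gap + l2))
        else:
            length = int(rng.integers(10, min(100, clen - start) + 1))
            blocks = ((start, start + length),)
        records.append(
            AlignmentRecord(
                read_id=f"r{ri}",
                contig_id=cid,
                start=start,
                aligned_blocks=blocks,
                sample_id=f"s{int(rng.integers(1, 4))}",
            )
        )
    return records, catalog
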