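import numpy as np
import pytest

from repnet.network import CloneSet, Clone
from repnet.synthetic import GroupSpec, SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort with adjacent tissue, reused by read-only tests."""
    cfg = SyntheticConfig(
        n_samples_per_group=4,
        n_adjacent_per_group=2,
        groups={"GRPA": GroupSpec(), "GRPB": GroupSpec(clonality=1.0)},
        seed=7,
    )
    return simulate_cohort(cfg)


def truth_clone_sets(cohort, chain="IGH"):
    """CloneSets reconstructed from the generator's own clone table."""
    out = {}
    cl = cohort.truth.clones
    for sid, block in cl[cl["chain"] == chain].groupby("sample_id"):
        clones = [
            Clone(r.v_gene, r.j_gene, (), int(r.reads))
            for r in block.itertuples()
        ]
        out[sid] = CloneSet(clones, sum(c.read_count for c in clones))
    return out


def random_records(rng, n, sample_id="S", chain="IGH", n_v=3, n_j=2,
                   lengths=(9, 12, 15), alphabet="ACGT"):
    """Random clonotype records concentrated enough to create edges."""
    from repnet.io import ClonotypeRecord

    records = []
    for _ in range(n):
        L = int(rng.choice(lengths))
        seq = "".join(rng.choice(list(alphabet), size=L))
        records.append(
            ClonotypeRecord(
                sample_id=sample_id,
                chain=chain,
                v_gene=f"{chain}V{rng.integers(1, n_v + 1)}-1",
                j_gene=f"{chain}J{rng.integers(1, n_j + 1)}",
                cdr3_nt=seq,
                read_count=int(rng.integers(1, 20)),
            )
        )
    # duplicate some with small mutations so clusters are non-trivial
    for rec in list(records[: n // 3]):
        seq = list(rec.cdr3_nt)
        pos = int(rng.integers(len(seq)))
        seq[pos] = rng.choice([b for b in alphabet if b != seq[pos]])
        records.append(
            type(rec)(
                sample_id=rec.sample_id,
                chain=rec.chain,
                v_gene=rec.v_gene,
                j_gene=rec.j_gene,
                cdr3_nt="".join(seq),
                read_count=int(rng.integers(1, 20)),
            )
        )
    return records
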