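import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msatune.msa_io import Alignment, ReferenceAlignment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment_of(seqs: dict[str, str], rng, extra_cols: int = 6) -> Alignment:
    """Place each sequence's residues into random increasing columns."""
    width = max(len(s) for s in seqs.values()) + int(rng.integers(0, extra_cols + 1))
    rows = []
    for rid, res in seqs.items():
        positions = np.sort(rng.choice(width, size=len(res), replace=False))
        row = ["-"] * width
        for p, c in zip(positions, res):
            row[p] = c
        rows.append((rid, "".join(row)))
    # drop all-gap columns so the Alignment invariants hold trivially
    keep = [j for j in range(width) if any(r[1][j] != "-" for r in rows)]
    rows = [(rid, "".join(g[j] for j in keep)) for rid, g in rows]
    return Alignment(rows)


def random_test_ref_pair(rng, max_rows: int = 6, max_cols: int = 30):
    """A random (test, reference) pair over the same ungapped sequences,
    where the reference defines at least one aligned residue pair."""
    for _ in range(100):
        n = int(rng.integers(2, max_rows + 1))
        seqs = {
            f"s{i}": "".join(
                rng.choice(list(AMINO), size=int(rng.integers(1, max_cols // 2 + 1)))
            )
            for i in range(n)
        }
        ref = random_alignment_of(seqs, rng)
        test = random_alignment_of(seqs, rng)
        if any(
            sum(c != "-" for c in col) >= 2
            for col in zip(*(g for _, g in ref.rows))
        ):
            return test, ReferenceAlignment(ref)
    raise RuntimeError("could not generate a scorable reference")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def aacd_ref():
    return ReferenceAlignment(Alignment([("s1", "AACD"), ("s2", "A-CD")]))


@pytest.fixture
def aacd_test():
    return Alignment([("s1", "AACD"), ("s2", "-ACD")])
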