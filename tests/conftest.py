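import numpy as np
import pytest

from patphylo.pipeline import run_pipeline
from patphylo.synthetic_data import CohortSpec, simulate_cohort

# ---------------------------------------------------------------------------
# independent six-frame ORF oracle (standard-table translation written from
# scratch: enumerate every (strand, frame, Met) and extend to the next stop)

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_AA = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
_COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_orfs(seq: str, min_aa: int, longest_per_stop: bool = True):
    """Brute-force ORF set: (strand, fwd_start, fwd_end, peptide, has_stop)."""
    seq = seq.upper()
    L = len(seq)
    found = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else oracle_revcomp(seq)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, L - 2, 3)]
            prots = ["X" if "N" in c else CODON_AA[c] for c in codons]
            claimed_stops = set()
            for mi, aa in enumerate(prots):
                if aa != "M":
                    continue
                j = mi
                while j < len(prots) and prots[j] != "*":
                    j += 1
                if longest_per_stop:
                    if j in claimed_stops:
                        continue
                    claimed_stops.add(j)
                pep = "".join(prots[mi:j])
                if len(pep) < min_aa:
                    continue
                has_stop = j < len(prots)
                a = frame + 3 * mi
                b = frame + 3 * (j + 1 if has_stop else j)
                if strand == "-":
                    a, b = L - b, L - a
                found.append((strand, a, b, pep, has_stop))
    return sorted(found)


def orfs_as_tuples(orfs):
    return sorted((o.strand, o.start, o.end, o.peptide, o.has_stop) for o in orfs)


def random_dna(rng: np.random.Generator, n: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(
        alphabet[i] for i in rng.choice(len(alphabet), size=n, p=p)
    )


# ---------------------------------------------------------------------------
# shared cohorts (session-scoped: the 474-genome run feeds several tests)


@pytest.fixture(scope="session")
def cohort20():
    return simulate_cohort(CohortSpec(n_genomes=20, seed=7))


@pytest.fixture(scope="session")
def result20(cohort20):
    return run_pipeline(cohort20)


@pytest.fixture(scope="session")
def cohort474():
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def result474(cohort474):
    return run_pipeline(cohort474)
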