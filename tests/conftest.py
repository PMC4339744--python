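import numpy as np
import pandas as pd
import pytest

from mfqls.pedigree_kinship import Pedigree, canonical_pedigree, kinship_from_pedigree

FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def make_pedigree(rows):
    """rows: (fid, iid, father, mother) tuples; sex/phenotype filled in."""
    full = [(f, i, fa, mo, 1, "-9") for f, i, fa, mo in rows]
    return Pedigree(pd.DataFrame(full, columns=FAM_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def template():
    return canonical_pedigree(1)


@pytest.fixture(scope="session")
def template_kinship(template):
    return kinship_from_pedigree(template)


@pytest.fixture
def trio():
    return make_pedigree(
        [("A", "dad", "0", "0"), ("A", "mom", "0", "0"), ("A", "kid", "dad", "mom")]
    )


def random_pedigree(rng, n_max=12):
    """Random valid single-family pedigree of at most n_max members."""
    n_founders = int(rng.integers(2, 5))
    rows = [("R", f"I{k}", "0", "0") for k in range(1, n_founders + 1)]
    ids = [r[1] for r in rows]
    while len(rows) < n_max and rng.random() < 0.8:
        fa, mo = rng.choice(len(ids), size=2, replace=False)
        child = f"I{len(ids) + 1}"
        rows.append(("R", child, ids[fa], ids[mo]))
        ids.append(child)
    return make_pedigree(rows)


def random_spd(rng, n, base=None):
    """Random symmetric positive definite matrix, well conditioned."""
    A = rng.standard_normal((n, n)) / np.sqrt(n)
    return A @ A.T + np.eye(n)
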