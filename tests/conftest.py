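import numpy as np
import pandas as pd
import pytest

from rareburden import CohortGenotypes
from rareburden.cohort import MISSING, SITE_COLUMNS
from rareburden.reproduce import published_pairs as _published_pairs


@pytest.fixture(scope="session")
def published_pairs():
    """The bundled 14-locus published frequency table as LocusFreqPair list."""
    return _published_pairs()


@pytest.fixture(scope="session")
def published_diffs(published_pairs):
    return np.array([p.diff for p in published_pairs])


def make_cohort(case_gts, control_gts, n_loci=None, genes=None, variant_ids=None):
    """Build a small cohort from explicit genotype rows (lists of dosages)."""
    geno = np.array(list(case_gts) + list(control_gts), dtype=np.int8)
    if geno.ndim == 1:
        geno = geno[:, None]
    n_loci = geno.shape[1]
    sites = pd.DataFrame(
        {
            "gene": genes or [f"G{j}" for j in range(n_loci)],
            "variant_id": variant_ids or [f"rs{j}" for j in range(n_loci)],
            "chrom": ["1"] * n_loci,
            "pos": list(range(100, 100 + n_loci)),
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
        },
        columns=SITE_COLUMNS,
    )
    n_case = len(case_gts)
    ids = [f"s{i}" for i in range(geno.shape[0])]
    is_case = np.array([i < n_case for i in range(geno.shape[0])])
    return CohortGenotypes(sites, geno, ids, is_case)


@pytest.fixture
def hand_cohort():
    """12 samples at one locus: among cases 2 missing, 2 het + 1 hom called."""
    case = [[1], [1], [2], [0], [0], [0], [0], [0], [0], [0], [MISSING], [MISSING]]
    control = [[0], [0], [0], [1]]
    return make_cohort(case, control)
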