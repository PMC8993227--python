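import numpy as np
import pandas as pd
import pytest

from patapa.de_stats import PACMatrix
from patapa.io_formats import GenomeSeq


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def flat_genome():
    """Two chromosomes of neutral (non-A-rich) sequence."""
    unit = "CGTCGTACGG"
    return GenomeSeq({"chr1": unit * 200, "chr2": unit * 200})


def make_matrix(ck: np.ndarray, st: np.ndarray, meta: pd.DataFrame | None = None) -> PACMatrix:
    """PACMatrix from raw CK/ST count blocks (units x replicates)."""
    ck = np.atleast_2d(ck)
    st = np.atleast_2d(st)
    n_ck, n_st = ck.shape[1], st.shape[1]
    cols = [f"CK_{i + 1}" for i in range(n_ck)] + [f"ST_{i + 1}" for i in range(n_st)]
    counts = pd.DataFrame(np.hstack([ck, st]), columns=cols)
    counts.index = pd.Index([f"u{i + 1}" for i in range(len(counts))], name="unit_id")
    design = pd.DataFrame(
        {
            "condition": ["CK"] * n_ck + ["ST"] * n_st,
            "replicate": list(range(1, n_ck + 1)) + list(range(1, n_st + 1)),
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return PACMatrix(counts=counts, design=design, meta=meta)


GFF_BODY = """##gff-version 3
chr1\ttest\tgene\t1\t1000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=geneA.1;Parent=geneA
chr1\ttest\texon\t1\t400\t.\t+\t.\tParent=geneA.1
chr1\ttest\texon\t501\t1000\t.\t+\t.\tParent=geneA.1
chr1\ttest\tfive_prime_UTR\t1\t100\t.\t+\t.\tParent=geneA.1
chr1\ttest\tCDS\t101\t400\t.\t+\t.\tParent=geneA.1
chr1\ttest\tCDS\t501\t800\t.\t+\t.\tParent=geneA.1
chr1\ttest\tthree_prime_UTR\t801\t1000\t.\t+\t.\tParent=geneA.1
chr1\ttest\tgene\t2001\t3000\t.\t+\t.\tID=geneB
chr1\ttest\tmRNA\t2001\t3000\t.\t+\t.\tID=geneB.1;Parent=geneB
chr1\ttest\texon\t2001\t3000\t.\t+\t.\tParent=geneB.1
chr1\ttest\tCDS\t2101\t3000\t.\t+\t.\tParent=geneB.1
chr2\ttest\tgene\t501\t1500\t.\t-\t.\tID=geneC
chr2\ttest\tmRNA\t501\t1500\t.\t-\t.\tID=geneC.1;Parent=geneC
chr2\ttest\texon\t501\t1500\t.\t-\t.\tParent=geneC.1
chr2\ttest\tthree_prime_UTR\t501\t700\t.\t-\t.\tParent=geneC.1
chr2\ttest\tCDS\t701\t1400\t.\t-\t.\tParent=geneC.1
chr2\ttest\tgene\t3001\t4000\t.\t+\t.\tID=geneD
chr2\ttest\tmRNA\t3001\t3900\t.\t+\t.\tID=geneD.1;Parent=geneD
chr2\ttest\texon\t3001\t3900\t.\t+\t.\tParent=geneD.1
chr2\ttest\tthree_prime_UTR\t3801\t3900\t.\t+\t.\tParent=geneD.1
chr2\ttest\tmRNA\t3001\t4000\t.\t+\t.\tID=geneD.2;Parent=geneD
chr2\ttest\texon\t3001\t4000\t.\t+\t.\tParent=geneD.2
chr2\ttest\tthree_prime_UTR\t3801\t4000\t.\t+\t.\tParent=geneD.2
"""


@pytest.fixture
def gff_file(tmp_path):
    path = tmp_path / "ann.gff3"
    path.write_text(GFF_BODY)
    return str(path)
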