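"""Shared fixtures: small programmatically generated datasets and files."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.genotype_io import GenotypeDataset, make_variant_table


@pytest.fixture
def tiny_phased_vcf(tmp_path):
    """A 3-variant, 2-sample fully phased VCF plus its breed table."""
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0|0\t0|1\n"
        "1\t300\trs3\tG\tA\t.\t.\t.\tGT\t1|0\t0|0\n"
    )
    breeds = tmp_path / "breeds.tsv"
    breeds.write_text("S1\tB1\nS2\tB2\n")
    return vcf, breeds


@pytest.fixture
def dataset_with_missing():
    """20-sample, 25-variant unphased dataset for QC exercises.

    Layout (MAF over 20 samples = 40 alleles unless noted):
      v2: single alt allele -> MAF 1/40, fails the 0.05 MAF filter;
      v4: missing in s18, s19, s20 (15% locus missingness; still 2/19 =
          10.5% after s20 is dropped);
      all other variants: alternating 0/1 genotypes, complete.
    Sample s20 misses v4, v5, v6 (3/25 = 12% > 5% -> removed first);
    s18 and s19 miss only v4 (4% <= 5% -> kept).
    """
    n = 20
    m = 25
    variants = make_variant_table(
        ["1"] * m, list(range(100, 100 + 100 * m, 100)),
        [f"v{i}" for i in range(1, m + 1)], ["A"] * m, ["G"] * m,
    )
    G = np.tile(np.array([0, 1] * (n // 2), dtype=np.int8), (m, 1))
    G[1] = [1] + [0] * (n - 1)       # v2: single alt allele
    G[3, 17] = G[3, 18] = G[3, 19] = -1   # v4 missing in s18..s20
    G[4, 19] = -1                    # s20 also misses v5, v6
    G[5, 19] = -1
    samples = [f"s{i}" for i in range(1, n + 1)]
    breed_of = {s: ("B1" if i < n // 2 else "B2") for i, s in enumerate(samples)}
    return GenotypeDataset(variants=variants, samples=samples, breed_of=breed_of, G=G)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
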