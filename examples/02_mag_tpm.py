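"""MAG-level TPM on a two-MAG toy: the summed-counts-over-summed-lengths
aggregation and the noncoding exclusion, by hand-checkable arithmetic."""

import pandas as pd

from magcoex import mag_tpm

quant = pd.DataFrame(
    [  # gene, sample, estimated count, effective length
        ("a1", "s1", 6, 100),
        ("a2", "s1", 4, 300),
        ("b1", "s1", 5, 50),
        ("a_rrna", "s1", 1_000_000, 1500),  # huge ribosomal signal
    ],
    columns=["gene_id", "sample_id", "est_count", "eff_length"],
)
meta = pd.DataFrame(
    {
        "gene_id": ["a1", "a2", "b1", "a_rrna"],
        "mag_id": ["A", "A", "B", "A"],
        "biotype": ["CDS", "CDS", "CDS", "rRNA"],
        "marker_families": [frozenset()] * 4,
    }
)

mat = mag_tpm(quant, meta)
print(mat.tpm.round(1))
# MAG A: q = 6+4 = 10 counts over l = 100+300 = 400 bases -> rate 0.025
# MAG B: q = 5 over l = 50 -> rate 0.100
# TPM = rate / (0.025 + 0.100) * 1e6 -> A = 200000, B = 800000.
# The million-count rRNA gene contributes nothing: noncoding RNAs are
# excluded from numerator and denominator alike.
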