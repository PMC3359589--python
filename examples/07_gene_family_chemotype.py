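"""Screen a synthetic strain for cannabinoid synthase family members and
call its chemotype.

The genome carries an intact THCAS-like gene and a frameshifted CBDAS-like
pseudogene: the expected call is THCA-dominant, mirroring how an intact
oxidocyclase on one branch of the family and pseudogenic copies on the other
determine whether a strain makes THCA or CBDA.
"""

import numpy as np

from cannaseq.gene_family import chemotype_call
from cannaseq.seqcore import NucSequence

rng = np.random.default_rng(11)
NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in ("TAA", "TAG", "TGA")]


def make_cds(n_codons):
    return "ATG" + "".join(
        NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n_codons - 2)
    ) + "TAA"


def rand(n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


thcas_ref = NucSequence("THCAS", make_cds(540))
cbdas_ref = NucSequence("CBDAS", make_cds(540))

broken_cbdas = cbdas_ref.seq[:450] + cbdas_ref.seq[451:]  # 1-bp deletion
scaffolds = [
    NucSequence("scaffoldA", rand(1500) + thcas_ref.seq + rand(1500)),
    NucSequence("scaffoldB", rand(1500) + broken_cbdas + rand(1500)),
]
transcripts = [NucSequence("flower_transcript", thcas_ref.seq)]

call, evidence = chemotype_call(scaffolds, transcripts, [thcas_ref], [cbdas_ref])
print("chemotype call:", call)
print(evidence[["family", "subject", "subject_kind", "identity_pct",
                "status", "n_frameshifts", "n_premature_stops"]].to_string(index=False))
# the frameshifted CBDAS copy explains CBDAS-derived reads without an intact gene
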