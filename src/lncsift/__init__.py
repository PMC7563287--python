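"""lncsift: classify transcripts as long non-coding RNA or mRNA.

The classifier works from sequence alone (no genome annotation): scalar
coding-potential features (ORF/CDS structure, Fickett TESTCODE, hexamer
log-likelihood, peptide properties), a tri-nucleotide significance screen
(two-sample Z with Benjamini–Hochberg FDR), Pearson-ranked incremental
feature selection, and a balanced random forest that tolerates the heavy
class imbalance typical of lncRNA catalogues.
"""

__version__ = "0.1.0"

from . import featsel, features, hexamer, metrics, model, pipeline, seqio, synth, trinuc_stats

__all__ = [
    "seqio",
    "features",
    "hexamer",
    "trinuc_stats",
    "featsel",
    "model",
    "metrics",
    "synth",
    "pipeline",
    "__version__",
]
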