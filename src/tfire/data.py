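"""Reference benchmark tables for 16 yeast transcription factors.

These are the curated inputs of the standard evaluation of structure-based
binding-site prediction on *Saccharomyces cerevisiae*: per-TF template
identifiers with site statistics, per-TF prediction confusion counts with
AUCs and rank bookkeeping, and per-TF PWM dissimilarity (psi) values of the
structure-derived PWM versus the uniform reference, both measured against the
curated JASPAR motif.  They serve as arithmetic inputs to the metric and
summary functions; they are counts and scores, not structures.
"""

from __future__ import annotations

# (tf, template chains, n_sites, n_orfs, n_residues, L_binding_site)
DATA_SUMMARY: list[tuple[str, str, int, int, int, int]] = [
    ("GAL4", "3coq_A,B", 15, 7, 178, 19),
    ("GCN4", "1ysa_C,D", 18, 11, 114, 16),
    ("HAP1", "1hwt_C,D,G,H", 9, 5, 287, 19),
    ("LEU3", "2ere_A,B", 5, 5, 120, 14),
    ("MATA1", "1yrn_A", 1, 1, 49, 13),
    ("MATALPHA2", "1apl_C", 10, 7, 59, 12),
    ("MCM1", "1mnm_A,B", 26, 21, 166, 20),
    ("MCM1_MATALPHA2", "1mnm_A,B,C,D", 1, 1, 320, 25),
    ("NDT80", "1mnn_A", 1, 1, 290, 13),
    ("PHO4", "1a0a_A,B", 4, 1, 126, 16),
    ("PPR1", "1pyi_A,B", 1, 1, 158, 14),
    ("PUT3", "1zme_C,D", 3, 2, 140, 14),
    ("RAP1", "1ign_A", 24, 18, 189, 18),
    ("TBP", "1ytb_A", 7, 4, 180, 12),
    ("TFIIA", "1ytf_C", 1, 1, 192, 13),
    ("TFIIA_TBP", "1ytf_A,C", 1, 1, 372, 15),
]

# Per-TF prediction outcome:
# (tf, tp, fn, fp, auc, n_top_sites, n_sites, n_top_orfs, n_orfs)
PREDICTION_BENCHMARK: list[tuple[str, int, int, int, float, int, int, int, int]] = [
    ("MCM1_MATALPHA2", 1, 0, 0, 1.00, 1, 1, 1, 1),
    ("PPR1", 1, 0, 0, 1.00, 1, 1, 1, 1),
    ("NDT80", 1, 0, 0, 1.00, 1, 1, 1, 1),
    ("LEU3", 5, 0, 0, 1.00, 5, 5, 5, 5),
    ("MATA1", 1, 0, 0, 1.00, 1, 1, 1, 1),
    ("TFIIA_TBP", 1, 0, 1, 0.91, 0, 1, 0, 1),
    ("GAL4", 12, 3, 0, 0.90, 12, 15, 7, 7),
    ("MCM1", 25, 1, 26, 0.86, 22, 26, 18, 21),
    ("MATALPHA2", 5, 5, 1, 0.83, 6, 10, 5, 7),
    ("TBP", 5, 2, 1, 0.81, 4, 7, 4, 4),
    ("PHO4", 4, 0, 10, 0.78, 1, 4, 1, 1),
    ("PUT3", 2, 1, 0, 0.76, 2, 3, 2, 2),
    ("GCN4", 7, 11, 2, 0.72, 8, 18, 5, 11),
    ("HAP1", 8, 1, 56, 0.68, 3, 9, 2, 5),
    ("RAP1", 3, 21, 0, 0.66, 11, 24, 8, 18),
    ("TFIIA", 1, 0, 6, 0.63, 0, 1, 0, 1),
]

# TFs shared with the de-novo motif-discovery comparison (the subset over
# which cross-method averages are taken).
DENOVO_COMPARISON_TFS: tuple[str, ...] = (
    "LEU3", "GAL4", "MCM1", "MATALPHA2", "TBP", "PUT3", "GCN4", "HAP1", "RAP1",
)

# psi dissimilarity to the curated JASPAR motif:
# (tf, structure-derived PWM, uniform Even-PWM)
PWM_SIMILARITY: list[tuple[str, float, float]] = [
    ("GAL4", 0.15, 0.32),
    ("GCN4", 0.12, 0.32),
    ("HAP1", 0.33, 0.40),
    ("LEU3", 0.22, 0.48),
    ("MATA1", 0.73, 0.70),
    ("MATALPHA2", 0.31, 0.64),
    ("MCM1", 0.34, 0.41),
    ("NDT80", 0.11, 0.44),
    ("PHO4", 0.19, 0.54),
    ("PUT3", 0.40, 0.52),
    ("RAP1", 0.49, 0.52),
    ("TBP", 0.17, 0.43),
]
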