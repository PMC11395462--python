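"""Reference molecular-function enrichment tables for the worked examples.

Two published top-25 drug-target lists for mesocorticolimbic disorders — one
of already-known (control) targets, one of novel predictions — were tested
for Gene Ontology molecular-function over-representation against a universe
of N = 15,288 annotated genes. Each row records the term, the observed hit
count r among the R = 25 targets, the term size n, the universe size N and
the reported hypergeometric tail probability.

These rows serve as fixed worked examples for the ``hypergeom_tail`` kernel:
recomputing p from (r, R, n, N) must reproduce the reported value to three
significant figures.
"""

from __future__ import annotations

from .enrichment_stats import EnrichmentRow

__all__ = ["CONTROL_TARGET_ENRICHMENT", "NOVEL_TARGET_ENRICHMENT", "reported_rows"]

# (term, r, R, n, N, reported p)
_CONTROL = [
    ("serotonin binding", 7, 25, 11, 15288, 4.08e-18),
    ("amine binding", 7, 25, 13, 15288, 2.12e-17),
    ("drug binding", 11, 25, 130, 15288, 4.4e-17),
    ("serotonin receptor activity", 7, 25, 15, 15288, 7.93e-17),
    ("G-protein coupled amine receptor activity", 7, 25, 42, 15288, 3.23e-13),
    ("transmembrane signaling receptor activity", 14, 25, 1196, 15288, 5.86e-10),
    ("dopamine binding", 4, 25, 10, 15288, 1.16e-9),
    ("signaling receptor activity", 14, 25, 1299, 15288, 1.74e-9),
    ("signal transducer activity", 15, 25, 1617, 15288, 2.55e-9),
    ("molecular transducer activity", 15, 25, 1617, 15288, 2.55e-9),
    ("dopamine neurotransmitter receptor activity, coupled via Gi/Go", 3, 25, 3, 15288, 3.86e-9),
    ("catecholamine binding", 4, 25, 14, 15288, 5.5e-9),
    ("G-protein coupled receptor activity", 11, 25, 812, 15288, 1.99e-8),
    ("receptor activity", 14, 25, 1583, 15288, 2.28e-8),
    ("dopamine neurotransmitter receptor activity", 3, 25, 5, 15288, 3.85e-8),
    ("extracellular ligand-gated ion channel activity", 5, 25, 74, 15288, 1.14e-7),
    ("excitatory extracellular ligand-gated ion channel activity", 4, 25, 49, 15288, 1.12e-6),
    ("ligand-gated channel activity", 5, 25, 145, 15288, 3.27e-6),
    ("ligand-gated ion channel activity", 5, 25, 145, 15288, 3.27e-6),
    ("neurotransmitter binding", 3, 25, 24, 15288, 7.64e-6),
]

_NOVEL = [
    ("voltage-gated cation channel activity", 11, 25, 138, 15288, 8.66e-17),
    ("voltage-gated calcium channel activity", 8, 25, 35, 15288, 3.35e-16),
    ("voltage-gated ion channel activity", 11, 25, 188, 15288, 2.78e-15),
    ("voltage-gated channel activity", 11, 25, 188, 15288, 2.78e-15),
    ("cation channel activity", 12, 25, 289, 15288, 6.93e-15),
    ("ion gated channel activity", 12, 25, 323, 15288, 2.63e-14),
    ("gated channel activity", 12, 25, 323, 15288, 2.63e-14),
    ("calcium channel activity", 9, 25, 109, 15288, 6.32e-14),
    ("calcium ion transmembrane transporter activity", 9, 25, 128, 15288, 2.77e-13),
    ("ion channel activity", 12, 25, 415, 15288, 5.17e-13),
    ("substrate-specific channel activity", 12, 25, 425, 15288, 6.85e-13),
    ("high voltage-gated calcium channel activity", 5, 25, 9, 15288, 9.58e-13),
    ("passive transmembrane transporter activity", 12, 25, 450, 15288, 1.34e-12),
    ("channel activity", 12, 25, 450, 15288, 1.34e-12),
    ("divalent inorganic cation transmembrane transporter activity", 9, 25, 155, 15288, 1.59e-12),
    ("transmembrane transporter activity", 15, 25, 972, 15288, 1.81e-12),
    ("cation transmembrane transporter activity", 13, 25, 618, 15288, 2.26e-12),
    ("ion transmembrane transporter activity", 14, 25, 825, 15288, 4.08e-12),
    ("metal ion transmembrane transporter activity", 11, 25, 401, 15288, 1.13e-11),
]

CONTROL_TARGET_ENRICHMENT: list[EnrichmentRow] = [EnrichmentRow(*row) for row in _CONTROL]
NOVEL_TARGET_ENRICHMENT: list[EnrichmentRow] = [EnrichmentRow(*row) for row in _NOVEL]


def reported_rows() -> list[EnrichmentRow]:
    """All worked-example rows (control then novel lists)."""
    return CONTROL_TARGET_ENRICHMENT + NOVEL_TARGET_ENRICHMENT
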