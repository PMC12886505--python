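"""Published worked-example numbers from the dsAllim / Orius similis case study.

The pipeline was developed around a risk assessment of dsAllim-expressing
cotton on the predatory bug *Orius similis*.  The raw sequencing reads of
that study are not needed here; its published summary counts serve as the
worked example for the table summarizers: per-level KEGG pathway counts
(nymph and adult transcriptomes) and per-match-length bin counts of genes
sharing contiguous matches with the dsRNA.

Each entry is ``(total, n_up, n_down, n_unchanged)``.
"""

from __future__ import annotations

#: KEGG pathway-proximity level counts, per life stage.
PATHWAY_LEVEL_COUNTS: dict[str, dict[int, tuple[int, int, int, int]]] = {
    "nymph": {
        1: (35, 17, 18, 0),
        2: (280, 47, 40, 193),
        3: (103, 23, 22, 58),
    },
    "adult": {
        1: (65, 15, 16, 34),
        2: (144, 30, 25, 89),
        3: (198, 27, 17, 154),
    },
}

#: Genes binned by longest contiguous match (bp) with the dsRNA; bin 15 = ">=15".
MATCH_BIN_COUNTS: dict[int, tuple[int, int, int, int]] = {
    7: (28744, 71, 91, 28582),
    8: (14237, 69, 58, 14110),
    9: (3847, 18, 21, 3808),
    10: (943, 5, 8, 930),
    11: (185, 2, 0, 183),
    12: (28, 1, 0, 27),
    13: (13, 0, 0, 13),
    14: (8, 0, 0, 8),
    15: (0, 0, 0, 0),
}

#: dsRNA concentration expressed in planta (ng per g fresh leaf) and the
#: worst-case multiplier used in the animal-feeding test.
IN_PLANTA_DSRNA_NG_PER_G = 4.4
MAX_HAZARD_FACTOR = 100.0

#: Length (bp) of the conserved target-gene domain used as the dsRNA trigger.
DSRNA_LENGTH_BP = 403
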