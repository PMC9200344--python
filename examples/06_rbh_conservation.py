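"""Normalized reciprocal-best-hit conservation scores.

Synthetic tabular BLASTP hits (the 12-column -outfmt 6 layout) for a
reference protein searched against three proteomes, and back. Scores are
reciprocal-best-hit bit scores divided by the reference self-hit bit
score; reciprocity failures score 0.
"""

import pandas as pd

from nemasrna.conservation import OUTFMT6_COLUMNS, SpeciesHits, score_matrix


def hits(rows):
    return pd.DataFrame(
        [(q, s, 90.0, 100, 2, 0, 1, 100, 1, 100, 1e-30, b) for q, s, b in rows],
        columns=OUTFMT6_COLUMNS,
    )


self_hits = hits([("LOTR1_REF", "LOTR1_REF", 500)])
species = [
    SpeciesHits("reference_self", self_hits, self_hits),
    SpeciesHits(
        "close_relative",
        hits([("LOTR1_REF", "cr_homolog", 320)]),
        hits([("cr_homolog", "LOTR1_REF", 310), ("cr_homolog", "other", 50)]),
    ),
    SpeciesHits(
        "distant_species",
        hits([("LOTR1_REF", "ds_tudor", 120)]),
        # reciprocal best hit is a different protein: reciprocity fails
        hits([("ds_tudor", "unrelated", 400), ("ds_tudor", "LOTR1_REF", 110)]),
    ),
]

matrix = score_matrix(species, ["LOTR1_REF"], {"LOTR1_REF": 500.0})
print(matrix.round(3).to_string())
print(
    "\n1.0 = the self proteome; 0.62 = a conserved reciprocal homolog "
    "(310/500);\n0.0 = the forward hit's own best match is another protein, "
    "so reciprocity fails."
)
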