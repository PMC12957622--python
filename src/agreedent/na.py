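"""Agreement on assessability: do observers agree on which teeth are NA?

A tooth can be unassessable on a panoramic radiograph (distortion,
superimposition).  Whether observers agree on *that* call is its own
reliability question: every rating is recoded to a binary alphabet
{notNA, NA} and unweighted Gwet's AC1 is computed over **all** cells — the
binary recoding removes missingness by construction, so no exclusion
applies and the observation totals equal units x raters.  AC1 is used
because NA is (by design) rare, the classic prevalence-imbalance situation
in which kappa-type coefficients collapse.

A descriptive audit flags any rater whose NA proportion exceeds 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import AgreementResult, gwet_ac
from .study import RatingMatrix, StagingScheme
from .weights import build_weights

#: binary assessability alphabet (order: available first)
NA_SCHEME_CATEGORIES = ("notNA", "NA")

NA_PREVALENCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class NAReport:
    ac1: AgreementResult
    na_count: int
    na_proportion: float
    per_rater_na_proportion: dict
    prevalence_flag: bool


def binarize_na(matrix: RatingMatrix) -> RatingMatrix:
    """Map every cell to 'NA' or 'notNA'; the output has no missing cells."""
    scheme = StagingScheme(
        "NA_BIN", NA_SCHEME_CATEGORIES, False, matrix.scheme.applicable_teeth
    )
    cells = np.where(matrix.notna_mask, "notNA", "NA").astype(object)
    return RatingMatrix(
        list(matrix.unit_ids), list(matrix.rater_ids), cells, scheme, session=matrix.session
    )


def na_agreement(matrix: RatingMatrix) -> NAReport:
    """AC1 on the binarized matrix plus the NA-prevalence audit."""
    binary = binarize_na(matrix)
    weights = build_weights(NA_SCHEME_CATEGORIES, "identity")
    ac1 = gwet_ac(binary, weights)
    na_cells = ~matrix.notna_mask
    total = matrix.cells.size
    per_rater = {
        str(r): float(na_cells[:, j].mean()) for j, r in enumerate(matrix.rater_ids)
    }
    return NAReport(
        ac1=ac1,
        na_count=int(na_cells.sum()),
        na_proportion=float(na_cells.sum() / total),
        per_rater_na_proportion=per_rater,
        prevalence_flag=any(p > NA_PREVALENCE_THRESHOLD for p in per_rater.values()),
    )
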