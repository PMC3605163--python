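"""Per-GO-term masking of the expression matrix and technique routing.

Each GO term in the term2probeset map masks the monolithic expression
matrix down to the P_X x N submatrix of its annotated probesets.  Subsets
overlap by construction (the DAG shares probesets across terms).  Small
subsets — where the variable count is roughly the sample count — need no
full model selection and are routed to a plain regularized least squares
(RLS) classification; the rest get the embedded l1l2 feature-selection
procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .integrate import TermProbesetMap
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

L1L2FS = "L1L2FS"
RLS = "RLS"


@dataclass
class TermSubset:
    """The masked expression submatrix for one GO term.

    Rows are exact copies of the source matrix rows; the column (sample)
    order is identical across all subsets.
    """

    term_id: str
    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # P_X x N
    technique: str

    @property
    def n_variables(self) -> int:
        return len(self.probeset_ids)


def route_technique(n_variables: int, n_samples: int, ratio_threshold: float = 1.0) -> str:
    """Pick the learning technique for a subset.

    A subset is *sufficiently small* — no full model selection needed —
    when P_X <= ratio_threshold * N (boundary inclusive); such subsets go
    to RLS, the rest to l1l2 feature selection.  Pure function of
    (P_X, N, threshold).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    return RLS if n_variables <= ratio_threshold * n_samples else L1L2FS


def generate_subsets(
    gedm: ExpressionMatrix,
    tpmap: TermProbesetMap,
    ratio_threshold: float = 1.0,
    min_probesets: int = 1,
) -> list[TermSubset]:
    """Mask the expression matrix once per mapped GO term.

    Returns one subset per term (sorted by term id for determinism); terms
    whose probesets all dropped out of the matrix are skipped with a log
    entry.  ``min_probesets`` optionally filters very small subsets
    (default keeps everything).
    """
    row_index = {pid: i for i, pid in enumerate(gedm.probeset_ids)}
    subsets: list[TermSubset] = []
    for term in sorted(tpmap.term_to_probesets):
        probesets = sorted(p for p in tpmap.term_to_probesets[term] if p in row_index)
        if not probesets:
            logger.info("term %s has no surviving probesets; skipped", term)
            continue
        if len(probesets) < min_probesets:
            logger.info(
                "term %s has %d probesets (< min_probesets=%d); skipped",
                term, len(probesets), min_probesets,
            )
            continue
        rows = gedm.values[[row_index[p] for p in probesets], :]
        subsets.append(
            TermSubset(
                term_id=term,
                probeset_ids=probesets,
                sample_ids=gedm.sample_ids,
                values=rows.copy(),
                technique=route_technique(len(probesets), gedm.n_samples, ratio_threshold),
            )
        )
    return subsets
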