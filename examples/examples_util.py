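"""Shared helper for the example scripts: one-call cohort classification."""

import numpy as np

from tmmscope import SsgseaEngine, classify, enrichment_matrix, permutation_null
from tmmscope.gene_sets import TEL_SUB_PATHWAYS


def classify_cohort(cohort, n_perm=2000, seed=0, fdr_threshold=0.5):
    engine = SsgseaEngine(cohort.expression)
    scores = enrichment_matrix(cohort.expression, cohort.gene_sets)
    rng = np.random.default_rng(seed)
    nulls = {}
    for name in ("ALT_CHR", *TEL_SUB_PATHWAYS):
        k = len(engine.member_indices(cohort.gene_sets[name].genes))
        nulls[name] = permutation_null(
            cohort.expression, set_size=k, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)), set_name=name, engine=engine,
        )
    return classify(scores, nulls, fdr_threshold=fdr_threshold)
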