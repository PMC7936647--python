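"""Context-normalized mutation rates.

Computes, for each labeled genomic compartment (exonic/intronic/intergenic,
repeat class, replication timing, chromatin state, nuclear localization, ...),
the number of mutations falling in the compartment normalized by the total
length of the regions assigned to it, reported on a log10 scale. A mutation
may be counted in several overlapping tracks (a site can be exonic AND
early-replicating); tracks may therefore be declared as a mutually exclusive
"partition" or as independent "overlay" annotations.

Zero-count contexts carry an explicit undefined marker (NaN log10 rate and
``rate_defined=False``) rather than a pseudocount or -inf.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .variants_io import LabeledIntervals, MutationRecord

__all__ = ["context_rates"]


def context_rates(
    records: Sequence[MutationRecord],
    contexts: Sequence[LabeledIntervals],
    track_group: str | None = None,
) -> pd.DataFrame:
    """Per-context mutation counts, per-bp rates, and log10 rates.

    Membership uses the 0-based half-open convention: a variant whose 0-based
    position equals an interval end is outside. Raises if a context has zero
    total length (its rate would be undefined by construction).
    """
    rows = []
    for ctx in contexts:
        if ctx.total_length <= 0:
            raise ValueError(f"context {ctx.label!r} has total length 0")
        count = sum(1 for r in records if ctx.contains(r.chrom, r.pos - 1))
        rate = count / ctx.total_length
        rows.append(
            {
                "context": ctx.label,
                "count": count,
                "length_bp": ctx.total_length,
                "rate": rate,
                "log10_rate": np.log10(rate) if count > 0 else np.nan,
                "rate_defined": count > 0,
            }
        )
    df = pd.DataFrame(rows)
    if track_group is not None:
        df.insert(0, "track_group", track_group)
    return df
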