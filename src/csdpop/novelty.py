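"""Worldwide-novelty classification of csd alleles.

An allele is *worldwide unique* when its amino-acid sequence matches no
entry in a user-supplied reference set of previously described alleles
(exact, case-insensitive string equality over the comparable fragment — no
alignment, mirroring the identity criterion used for allele definition).
The 2x2 rare-vs-frequent contingency table asks whether unique alleles are
over-represented among alleles restricted to a single apiary, the signature
of recently generated alleles that have not yet spread.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequences import AlleleRecord

__all__ = ["classify_novelty", "rare_frequent_table"]

logger = logging.getLogger(__name__)

NOVELTY_COLUMNS = ["allele_id", "aa_seq", "n_apiaries", "is_unique"]


def _normalise(seq: str) -> str:
    return seq.strip().upper()


def classify_novelty(
    alleles: Sequence[AlleleRecord],
    reference: Iterable[str],
    n_apiaries: Mapping[str, int],
) -> pd.DataFrame:
    """Classify each allele as worldwide-unique or already known.

    Parameters
    ----------
    alleles
        Distinct alleles to classify (one record per identity class).
    reference
        Amino-acid sequences of previously described alleles, trimmed to a
        comparable region.  An empty reference classifies everything unique
        and logs a warning.
    n_apiaries
        Number of apiaries each allele was identified in, keyed by allele id.

    Returns a table with columns allele_id, aa_seq, n_apiaries, is_unique.
    """
    known = {_normalise(s) for s in reference}
    if not known:
        logger.warning("empty reference set: every allele classified as unique")
    rows = []
    for rec in alleles:
        if rec.id not in n_apiaries:
            raise ValueError(f"no apiary count for allele {rec.id!r}")
        n_ap = int(n_apiaries[rec.id])
        if n_ap < 1:
            raise ValueError(f"allele {rec.id!r}: n_apiaries must be >= 1")
        rows.append(
            {
                "allele_id": rec.id,
                "aa_seq": rec.aa_seq,
                "n_apiaries": n_ap,
                "is_unique": _normalise(rec.aa_seq) not in known,
            }
        )
    return pd.DataFrame(rows, columns=NOVELTY_COLUMNS)


def rare_frequent_table(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """2x2 partition: one-apiary vs multi-apiary against unique vs known.

    Returns ``(counts, proportions)``: the contingency table (rows
    ``one_apiary`` / ``multi_apiary``, columns ``unique`` / ``known``) and
    the per-row proportion of worldwide-unique alleles, rounded to two
    decimals.  Raises ``ValueError`` on an empty table.
    """
    if table.empty:
        raise ValueError("empty novelty table")
    rare = table["n_apiaries"] == 1
    counts = pd.DataFrame(
        {
            "unique": [
                int((rare & table["is_unique"]).sum()),
                int((~rare & table["is_unique"]).sum()),
            ],
            "known": [
                int((rare & ~table["is_unique"]).sum()),
                int((~rare & ~table["is_unique"]).sum()),
            ],
        },
        index=["one_apiary", "multi_apiary"],
    )
    row_totals = counts.sum(axis=1)
    proportions = (counts["unique"] / row_totals).fillna(0.0).round(2)
    proportions.name = "proportion_unique"
    return counts, proportions
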