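"""Per-compound bioactivity scoring for activity-guided fractionation.

The score averages, over the n accessions of the panel, the product of a
compound's relative peak area a(i) (% of GC signal in accession i's oil)
and the germination inhibition g(i) (%) caused by that oil:

    B = (1/n) * sum_i a(i) * g(i)

A compound making up 100% of every oil, with every oil fully inhibitory,
scores the ceiling of 10,000. The score is descriptive — it carries no
p-value — and is computed on raw (unrenormalized) peak areas. Mildly
negative sampled inhibitions are clamped to 0 inside the score, since the
formula presumes inhibition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import AbundanceMatrix

SCORE_CEILING = 10_000.0


@dataclass
class BioactivityTable:
    """Per-compound scores with the per-accession a(i)*g(i) breakdown."""

    scores: pd.Series  # index: compound, value: B
    terms: pd.DataFrame  # compounds x accessions, entries a(i)*g(i)
    n: int

    def ranked(self) -> pd.Series:
        order = sorted(
            self.scores.index, key=lambda c: (-self.scores[c], c)
        )
        return self.scores.loc[order]


def bioactivity_score(
    am: AbundanceMatrix, g: dict[str, float] | pd.Series
) -> BioactivityTable:
    """Score every compound of the abundance matrix.

    ``g`` maps each accession to the germination inhibition (%) of its oil.
    Accessions missing from ``g`` are an error; negative inhibitions warn
    and are clamped to 0.
    """
    g = pd.Series(g, dtype=float)
    missing = [acc for acc in am.accessions if acc not in g.index]
    if missing:
        raise KeyError(f"no inhibition value for accession(s): {missing}")
    gv = g.loc[am.accessions].to_numpy()
    if np.any(gv < 0):
        warnings.warn(
            "negative inhibition values clamped to 0 for scoring",
            stacklevel=2,
        )
        gv = np.clip(gv, 0.0, None)
    terms = am.a.T * gv  # (n_compounds, n_accessions)
    scores = terms.sum(axis=1) / am.n
    return BioactivityTable(
        scores=pd.Series(scores, index=am.compounds, name="B"),
        terms=pd.DataFrame(terms, index=am.compounds, columns=am.accessions),
        n=am.n,
    )


@dataclass
class CandidateRanking:
    candidates: pd.Series  # descending B, ties broken by name
    excluded: pd.Series  # excluded compounds with their scores

    def tied_groups(self) -> list[list[str]]:
        groups: dict[float, list[str]] = {}
        for name, score in self.candidates.items():
            groups.setdefault(score, []).append(name)
        return [g for g in groups.values() if len(g) > 1]


def rank_candidates(
    bt: BioactivityTable, exclude: set[str] | None = None
) -> CandidateRanking:
    """Rank compounds by descending score.

    ``exclude`` removes known positives (e.g. a positive-control compound)
    from the candidate list; they are reported separately, never dropped
    silently.
    """
    if len(bt.scores) == 0:
        raise ValueError("empty bioactivity table")
    exclude = exclude or set()
    ranked = bt.ranked()
    mask = ranked.index.isin(exclude)
    return CandidateRanking(candidates=ranked[~mask], excluded=ranked[mask])


def heatmap_matrix(am: AbundanceMatrix, bt: BioactivityTable) -> pd.DataFrame:
    """Display matrix: compounds (rows, by descending B) x accessions, raw
    a(i) values, with the score as a final column. No normalization."""
    order = list(bt.ranked().index)
    if set(order) != set(am.compounds):
        raise ValueError("compound sets of matrix and score table differ")
    df = am.to_frame().T.loc[order]
    df["score"] = bt.scores.loc[order]
    return df
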