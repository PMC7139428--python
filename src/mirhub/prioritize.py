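"""Selection of validation candidates from the target-hub set.

The rule combines network sign and pathway context: every hub whose
node strength is negative (net repression released or reinforced in one
direction, i.e. the clearest prediction of a target expression change)
is selected unconditionally, and the positive-strength hubs are ranked
by the highest fold enrichment among significant GO terms annotating
them, with the top ``n_positive`` taken.
"""

from __future__ import annotations

import warnings
from typing import Sequence
from dataclasses import dataclass, field

from mirhub.enrichment import EnrichmentResult
from mirhub.network import HubReport, SignedNetwork

__all__ = ["SelectionReport", "select_candidates"]


@dataclass
class SelectionReport:
    hubs_considered: list[tuple[str, int]]  # (gene, strength)
    selected_negative: list[str]
    selected_positive: list[str]
    rationale: dict[str, str] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return self.selected_negative + self.selected_positive


def _best_term(
    gene: str, enrichment: Sequence[EnrichmentResult], alpha: float
) -> tuple[float, float, str] | None:
    """(fold, p, term) of the best significant term annotating ``gene``."""
    best: tuple[float, float, str] | None = None
    for r in enrichment:
        if r.p_adjusted >= alpha:
            continue
        if gene not in r.genes_hit:
            continue
        cand = (r.fold_enrichment, r.p_value, r.term_id)
        if best is None or (-cand[0], cand[1], cand[2]) < (-best[0], best[1], best[2]):
            best = cand
    return best


def select_candidates(
    hubs: HubReport,
    net: SignedNetwork,
    enrichment: Sequence[EnrichmentResult],
    n_positive: int = 3,
    alpha: float = 0.05,
) -> SelectionReport:
    """Apply the strength / fold-enrichment selection rule.

    Negative-strength hubs are all selected.  Positive-strength hubs are
    ranked by the maximum fold enrichment over significant terms that
    annotate them (ties: smaller term p, then gene symbol) and the top
    ``n_positive`` qualifying genes are selected; fewer qualifying than
    requested selects them all with a warning.  The result is invariant
    to the input order of hubs and enrichment rows.
    """
    if n_positive < 0:
        raise ValueError("n_positive must be non-negative")
    if not hubs.hubs:
        raise ValueError("empty hub report")

    considered = sorted((g, s) for g, _, s in hubs.hubs)
    rationale: dict[str, str] = {}

    negative = sorted(g for g, _, s in hubs.hubs if s < 0)
    for g in negative:
        rationale[g] = f"strength {dict(considered)[g]} < 0: selected unconditionally"

    positives = sorted(g for g, _, s in hubs.hubs if s > 0)
    ranked: list[tuple[float, float, str]] = []
    for g in positives:
        best = _best_term(g, enrichment, alpha)
        if best is None:
            rationale[g] = "strength > 0 but no significant annotating term: not eligible"
            continue
        fold, p, term = best
        ranked.append((fold, p, g))
        rationale[g] = f"strength > 0; best significant term {term} (fold {fold:.3g}, p {p:.3g})"
    ranked.sort(key=lambda t: (-t[0], t[1], t[2]))
    if len(ranked) < n_positive:
        warnings.warn(
            f"only {len(ranked)} positive hubs qualify (requested {n_positive})",
            UserWarning,
            stacklevel=2,
        )
    chosen_positive = [g for _, _, g in ranked[:n_positive]]
    for g in chosen_positive:
        rationale[g] += ": selected"

    return SelectionReport(
        hubs_considered=considered,
        selected_negative=negative,
        selected_positive=chosen_positive,
        rationale=rationale,
    )
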