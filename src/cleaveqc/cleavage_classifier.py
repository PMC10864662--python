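"""Tryptic/nontryptic terminus classification and per-sample protease-activity statistics.

A peptide terminus is *tryptic* when the residue N-terminal to the cleavage
site (the P1 residue) is Lys or Arg; otherwise the cleavage was made by
something other than trypsin and the terminus is *nontryptic* — the signature
of endogenous protease activity during sample handling. Nontryptic events are
attributed to protease-specificity classes by their P1 residue: the neutrophil
serine proteases ELANE/PRTN3 cleave after Ala/Ile/Val (not Leu) while CTSG
cleaves after Trp/Leu/Phe/Tyr.

Protein termini (and translation-derived N-terminal states: initiator-Met
removal, N-terminal acetylation) are not proteolytic events and count as
tryptic-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import PeptideObservation, RunConfig

TRYPTIC = "tryptic"
NONTRYPTIC = "nontryptic"
PROTEIN_TERMINUS = "protein_terminus"
OTHER_CLASS = "other"
NOT_APPLICABLE = "n/a"


@dataclass(frozen=True)
class TerminusCall:
    side: str  # "N" or "C"
    status: str  # tryptic | nontryptic | protein_terminus
    p1_residue: str
    protease_class: str


@dataclass(frozen=True)
class PeptideClassification:
    observation: PeptideObservation
    n_call: TerminusCall
    c_call: TerminusCall
    category: str  # fully_tryptic | nontryptic
    n_nontryptic_events: int


@dataclass
class SampleSummary:
    sample_id: str
    total_intensity: float
    nontryptic_intensity: float
    pct_nontryptic_intensity: float
    n_tryptic_peptides: int
    n_nontryptic_peptides: int
    class_intensity: dict[str, float]
    class_fraction_by_count: dict[str, float]
    class_fraction_by_intensity: dict[str, float]
    p1_frequency: dict[str, int]
    n_proteins_ge2_tryptic: int


def _attribute_class(p1: str, config: RunConfig) -> str:
    for name, residues in config.protease_classes.items():
        if p1 in residues:
            return name
    return OTHER_CLASS


def _is_nterm_acetylated(obs: PeptideObservation) -> bool:
    return any(
        m.position <= 1 and "acetyl" in m.name.lower() for m in obs.modifications
    )


def classify_peptide(obs: PeptideObservation, config: RunConfig) -> PeptideClassification:
    """Classify both termini of one mapped peptide observation.

    N side: protein start (start 1, or start 2 behind an initiator Met, or an
    N-terminally acetylated peptide) is a protein terminus; otherwise the
    preceding residue decides tryptic vs nontryptic. C side: the peptide's own
    last residue is the P1 of its C-terminal cleavage; a ``-`` following
    residue marks the protein C terminus.
    """
    preceding = obs.preceding_residue
    if preceding == "":
        raise ValueError(f"observation {obs.peptide!r} has no flanking context (unmapped)")

    # N terminus
    if (
        obs.start == 1
        or preceding == "-"
        or (obs.start == 2 and preceding == "M")
        or _is_nterm_acetylated(obs)
    ):
        n_call = TerminusCall("N", PROTEIN_TERMINUS, preceding, NOT_APPLICABLE)
    elif preceding in config.tryptic_residues:
        n_call = TerminusCall("N", TRYPTIC, preceding, NOT_APPLICABLE)
    else:
        n_call = TerminusCall("N", NONTRYPTIC, preceding, _attribute_class(preceding, config))

    # C terminus: last residue of the peptide is the P1 residue.
    last = obs.peptide[-1]
    if last in config.tryptic_residues:
        c_call = TerminusCall("C", TRYPTIC, last, NOT_APPLICABLE)
    elif obs.following_residue == "-":
        c_call = TerminusCall("C", PROTEIN_TERMINUS, last, NOT_APPLICABLE)
    else:
        c_call = TerminusCall("C", NONTRYPTIC, last, _attribute_class(last, config))

    n_events = sum(c.status == NONTRYPTIC for c in (n_call, c_call))
    if config.strict_nontryptic:
        category = NONTRYPTIC if n_events == 2 else "fully_tryptic"
    else:
        category = NONTRYPTIC if n_events >= 1 else "fully_tryptic"
    return PeptideClassification(obs, n_call, c_call, category, n_events)


def classify_observations(
    observations: Iterable[PeptideObservation], config: RunConfig
) -> list[PeptideClassification]:
    return [classify_peptide(o, config) for o in observations]


def summarize_sample(
    classifications: Sequence[PeptideClassification],
    sample_id: str,
    config: RunConfig,
) -> SampleSummary:
    """Aggregate one sample's classifications into activity statistics.

    A peptide with two nontryptic termini contributes two events to the class
    and P1 tallies but its intensity once to ``nontryptic_intensity``.
    Peptide intensity is the summed feature area over observations sharing
    (sequence, modifications); ``n_proteins_ge2_tryptic`` counts proteins with
    at least two distinct fully-tryptic peptide sequences.
    """
    cls = [c for c in classifications if c.observation.sample_id == sample_id]
    if not cls:
        raise ValueError(f"no classifications for sample {sample_id!r}")
    total = sum(c.observation.intensity for c in cls)
    if total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total intensity")

    nontryptic_intensity = 0.0
    class_intensity: dict[str, float] = {}
    class_counts: dict[str, int] = {}
    p1_frequency: dict[str, int] = {}
    tryptic_seqs: set[str] = set()
    nontryptic_seqs: set[str] = set()
    tryptic_by_protein: dict[str, set[str]] = {}

    for c in cls:
        obs = c.observation
        if c.category == NONTRYPTIC:
            nontryptic_intensity += obs.intensity
            nontryptic_seqs.add(obs.peptide)
            for call in (c.n_call, c.c_call):
                if call.status == NONTRYPTIC:
                    p1_frequency[call.p1_residue] = p1_frequency.get(call.p1_residue, 0) + 1
                    class_counts[call.protease_class] = class_counts.get(call.protease_class, 0) + 1
                    class_intensity[call.protease_class] = (
                        class_intensity.get(call.protease_class, 0.0) + obs.intensity
                    )
        else:
            tryptic_seqs.add(obs.peptide)
            tryptic_by_protein.setdefault(obs.protein_accession, set()).add(obs.peptide)

    n_events = sum(class_counts.values())
    sum_class_intensity = sum(class_intensity.values())
    class_fraction_by_count = (
        {k: v / n_events for k, v in class_counts.items()} if n_events else {}
    )
    class_fraction_by_intensity = (
        {k: v / sum_class_intensity for k, v in class_intensity.items()}
        if sum_class_intensity > 0
        else {}
    )
    return SampleSummary(
        sample_id=sample_id,
        total_intensity=total,
        nontryptic_intensity=nontryptic_intensity,
        pct_nontryptic_intensity=100.0 * nontryptic_intensity / total,
        n_tryptic_peptides=len(tryptic_seqs),
        n_nontryptic_peptides=len(nontryptic_seqs),
        class_intensity=class_intensity,
        class_fraction_by_count=class_fraction_by_count,
        class_fraction_by_intensity=class_fraction_by_intensity,
        p1_frequency=p1_frequency,
        n_proteins_ge2_tryptic=sum(
            1 for seqs in tryptic_by_protein.values() if len(seqs) >= 2
        ),
    )


def summarize_all_samples(
    classifications: Sequence[PeptideClassification], config: RunConfig
) -> list[SampleSummary]:
    samples = sorted({c.observation.sample_id for c in classifications})
    return [summarize_sample(classifications, s, config) for s in samples]


def summaries_to_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "sample_id": s.sample_id,
                "total_intensity": s.total_intensity,
                "nontryptic_intensity": s.nontryptic_intensity,
                "pct_nontryptic_intensity": s.pct_nontryptic_intensity,
                "n_tryptic_peptides": s.n_tryptic_peptides,
                "n_nontryptic_peptides": s.n_nontryptic_peptides,
                "n_proteins_ge2_tryptic": s.n_proteins_ge2_tryptic,
            }
        )
    return pd.DataFrame(rows)


def specificity_profile(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    """Long-format per-sample specificity table.

    One block of rows per protease class (kind="class") with count- and
    intensity-weighted fractions, and one per P1 residue (kind="p1_residue").
    Fractions sum to 1 per sample per weighting whenever events exist.
    """
    if not summaries:
        raise ValueError("need at least one sample summary")
    rows = []
    for s in summaries:
        n_events = sum(s.p1_frequency.values())
        for cls in sorted(set(s.class_fraction_by_count) | set(s.class_intensity)):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "kind": "class",
                    "key": cls,
                    "count": round(s.class_fraction_by_count.get(cls, 0.0) * n_events),
                    "intensity": s.class_intensity.get(cls, 0.0),
                    "fraction_by_count": s.class_fraction_by_count.get(cls, 0.0),
                    "fraction_by_intensity": s.class_fraction_by_intensity.get(cls, 0.0),
                }
            )
        for res, cnt in sorted(s.p1_frequency.items()):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "kind": "p1_residue",
                    "key": res,
                    "count": cnt,
                    "intensity": float("nan"),
                    "fraction_by_count": cnt / n_events if n_events else 0.0,
                    "fraction_by_intensity": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def classify_shared_peptide(
    obs: PeptideObservation,
    occurrences: Sequence[tuple[str, int, int, str, str]],
    config: RunConfig,
) -> PeptideClassification:
    """Classify a peptide found in several proteins, taking the most tryptic reading.

    Each occurrence supplies its own flanks; when the resulting calls conflict
    the interpretation with the fewest nontryptic events wins (conservative
    against overcalling protease activity). Ties break deterministically by
    (accession, start).
    """
    if not occurrences:
        raise ValueError(f"peptide {obs.peptide!r} maps to no protein")
    best = None
    best_key = None
    for acc, start, end, pre, post in sorted(occurrences):
        candidate = PeptideObservation(
            sample_id=obs.sample_id,
            peptide=obs.peptide,
            protein_accession=acc,
            start=start,
            end=end,
            preceding_residue=pre,
            following_residue=post,
            modifications=obs.modifications,
            intensity=obs.intensity,
            reporter_intensities=obs.reporter_intensities,
        )
        cls = classify_peptide(candidate, config)
        statuses = (cls.n_call.status, cls.c_call.status)
        key = (cls.n_nontryptic_events, sum(s == PROTEIN_TERMINUS for s in statuses))
        if best_key is None or key < best_key:
            best, best_key = cls, key
    return best


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    defined: bool = True


def correlate_activity(
    protein_abundance: Mapping[str, float],
    summaries: Sequence[SampleSummary],
    protease_class: Optional[str] = None,
) -> CorrelationResult:
    """Pearson correlation of a protease's abundance with nontryptic intensity.

    Pairs samples present in both inputs. ``protease_class`` restricts the
    nontryptic intensity to events of one specificity class. Zero variance in
    either vector yields an undefined (flagged) result.
    """
    paired = [s for s in summaries if s.sample_id in protein_abundance]
    if len(paired) < 3:
        raise ValueError("need >= 3 paired samples for a correlation")
    x = np.array([protein_abundance[s.sample_id] for s in paired], dtype=float)
    if protease_class is None:
        y = np.array([s.nontryptic_intensity for s in paired], dtype=float)
    else:
        y = np.array([s.class_intensity.get(protease_class, 0.0) for s in paired], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), len(paired), float("nan"), defined=False)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), len(paired), float(p))
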