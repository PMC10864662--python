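"""Synthetic proteomics data with known ground truth.

The generator emulates the experimental situation the pipeline analyzes:
proteins with log-normal abundances are digested by trypsin (LysC+trypsin is
one {K,R} rule), and in each sample a contaminating endogenous protease with a
configurable P1 specificity redistributes a fraction *a* (the activity) of
each cleavable tryptic peptide's intensity into nontryptic products. A
simulated serine-protease-inhibitor (DFP) treatment multiplies the activity by
``inhibition_factor`` in designated samples. Carving follows the
tryptic-sparing mechanism: most nontryptic products are sub-fragments of a
tryptic parent; the remainder cross a tryptic boundary into the neighbouring
peptide. Active-site serines carry an inhibitor adduct at a set occupancy in
treated samples. Reporter matrices add per-channel condition fold changes and
reference-pool channels.

Every random draw is seeded; the emitted ledger records all pre-noise truths
(nontryptic intensity shares, P1 event composition, occupancies, fold changes,
per-peptide provenance) for parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .digestion import ELANE_PRTN3_RULE, TRYPSIN_P, ProteaseRule, cleavage_sites, digest
from .io_formats import (
    Modification,
    PeptideObservation,
    ProteinRecord,
    observations_to_frame,
    write_fasta,
)
from .adduct_analysis import DFP_ADDUCT
from .tmt_quant import ReporterMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Relative intensity weight of a missed-cleavage tryptic form vs the 0-missed form.
MISSED_CLEAVAGE_WEIGHT = 0.25


@dataclass
class TMTSimConfig:
    sample_channels: list[str] = field(
        default_factory=lambda: [f"ch{i}" for i in range(1, 7)]
    )
    reference_channels: list[str] = field(default_factory=lambda: ["ref1", "ref2"])
    reporter_noise_cv: float = 0.1
    psm_per_peptide_mean: float = 1.5  # n_psm = 1 + Poisson(mean - 1)
    fraction_changed: float = 0.1
    log2fc_magnitude: float = 1.0


@dataclass
class AdductSpec:
    accession: str
    position: int  # 1-based, forced to Ser in the generated proteome
    occupancy: float
    n_features: int = 10
    localization_score: float = 40.0


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults mirror the emulated experiment."""

    n_proteins: int = 200
    protein_length_range: tuple[int, int] = (80, 240)
    abundance_lognormal: tuple[float, float] = (13.0, 1.0)  # (mu, sigma) of ln intensity
    protease_activity: dict[str, float] = field(
        default_factory=lambda: {
            "untreated_1": 0.25, "untreated_2": 0.25, "untreated_3": 0.25,
            "dfp_1": 0.25, "dfp_2": 0.25, "dfp_3": 0.25,
        }
    )
    endogenous_rule: ProteaseRule = field(default_factory=lambda: ELANE_PRTN3_RULE)
    dfp_samples: frozenset[str] = frozenset({"dfp_1", "dfp_2", "dfp_3"})
    inhibition_factor: float = 0.05
    tryptic_sparing_fraction: float = 0.8
    detectability_dropout: float = 0.1
    intensity_noise_cv: float = 0.1
    max_missed_cleavages: int = 1
    length_range: tuple[int, float] = (6, 45)
    residue_frequencies: Optional[dict[str, float]] = None
    tmt: TMTSimConfig = field(default_factory=TMTSimConfig)
    adducts: list[AdductSpec] = field(default_factory=list)
    seed: int = 20240112

    def effective_activity(self, sample: str) -> float:
        a = self.protease_activity[sample]
        if sample in self.dfp_samples:
            a *= self.inhibition_factor
        return a


@dataclass
class SyntheticLedger:
    """Ground truth emitted alongside the synthetic tables (pre-noise scale)."""

    total_intensity: dict[str, float] = field(default_factory=dict)
    nontryptic_intensity: dict[str, float] = field(default_factory=dict)
    p1_event_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    occupancies: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def nontryptic_share(self, sample: str) -> float:
        tot = self.total_intensity.get(sample, 0.0)
        return self.nontryptic_intensity.get(sample, 0.0) / tot if tot > 0 else 0.0

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.provenance)


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def generate_proteome(
    config: SimulationConfig, fasta_path=None
) -> list[ProteinRecord]:
    """Seeded i.i.d.-residue proteome; adduct positions are forced to serine."""
    rng = np.random.default_rng(config.seed)
    if config.residue_frequencies is None:
        letters, probs = list(AMINO_ACIDS), None
    else:
        letters = list(config.residue_frequencies)
        total = sum(config.residue_frequencies.values())
        probs = [config.residue_frequencies[l] / total for l in letters]
    lo, hi = config.protein_length_range
    forced: dict[str, dict[int, str]] = {}
    for spec in config.adducts:
        forced.setdefault(spec.accession, {})[spec.position] = "S"
    records = []
    for i in range(config.n_proteins):
        acc = f"SYN{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=length, p=probs)
        for pos, res in forced.get(acc, {}).items():
            if pos > length:
                raise ValueError(f"adduct position {pos} beyond {acc} length {length}")
            seq[pos - 1] = res
        records.append(ProteinRecord(acc, "".join(seq)))
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    return records


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def _flanks(seq: str, start: int, end: int) -> tuple[str, str]:
    pre = seq[start - 2] if start > 1 else "-"
    post = seq[end] if end < len(seq) else "-"
    return pre, post


def generate_observations(
    proteome: Sequence[ProteinRecord], config: SimulationConfig
) -> tuple[list[PeptideObservation], SyntheticLedger]:
    """Emit per-sample peptide features plus the ground-truth ledger.

    Per tryptic carrier peptide with internal endogenous cleavage sites, a
    fraction ``effective_activity(sample)`` of its intensity is redistributed:
    ``tryptic_sparing_fraction`` of it to the peptide's own endogenous
    sub-fragments (length-proportional), the remainder to a single
    boundary-crossing semi-tryptic product ending at the next tryptic boundary
    (folded back into internal fragments when the carrier ends the protein).
    Dropout and multiplicative log-normal noise are applied last; the ledger
    is tallied pre-noise and pre-dropout.
    """
    rng = np.random.default_rng(config.seed + 1)
    ledger = SyntheticLedger()
    samples = sorted(config.protease_activity)
    for s in samples:
        ledger.total_intensity[s] = 0.0
        ledger.nontryptic_intensity[s] = 0.0
        ledger.p1_event_counts[s] = {}
        ledger.occupancies[s] = {}

    adduct_carriers: dict[str, list[tuple[AdductSpec, "object"]]] = {}
    observations: list[PeptideObservation] = []

    abundances = {
        rec.accession: float(
            rng.lognormal(config.abundance_lognormal[0], config.abundance_lognormal[1])
        )
        for rec in proteome
    }

    for rec in proteome:
        seq = rec.sequence
        carriers = digest(
            rec, TRYPSIN_P, config.max_missed_cleavages, config.length_range
        )
        if not carriers:
            continue
        tryptic_bounds = [0] + cleavage_sites(rec, TRYPSIN_P) + [len(seq)]
        abundance = abundances[rec.accession]

        # reserve one 0-missed carrier per adduct site on this protein
        reserved: set[tuple[int, int]] = set()
        for spec in config.adducts:
            if spec.accession != rec.accession:
                continue
            cover = [c for c in carriers if c.start <= spec.position <= c.end]
            cover0 = [c for c in cover if c.missed_cleavages == 0]
            if not cover0:
                raise ValueError(
                    f"no 0-missed tryptic peptide covers adduct site "
                    f"{spec.accession}:{spec.position} (length filter too tight?)"
                )
            adduct_carriers.setdefault(rec.accession, []).append((spec, cover0[0]))
            # every covering form is rerouted through the feature pairs, so the
            # site's unmodified intensity comes only from the (1-theta) branch
            reserved.update((c.start, c.end) for c in cover)

        for carrier in carriers:
            key = (carrier.start, carrier.end)
            base_intensity = abundance * (MISSED_CLEAVAGE_WEIGHT ** carrier.missed_cleavages)
            if key in reserved:
                continue  # rerouted through adduct feature pairs below
            endo_sites = cleavage_sites(carrier.peptide, config.endogenous_rule)
            for sample in samples:
                a = config.effective_activity(sample)
                emissions: list[dict] = []  # peptide rows pre-noise for this carrier/sample
                if not endo_sites or a <= 0:
                    emissions.append(
                        dict(start=carrier.start, end=carrier.end,
                             intensity=base_intensity, kind="parent")
                    )
                else:
                    carve_total = a * base_intensity
                    parent_left = base_intensity - carve_total
                    if parent_left > 0:
                        emissions.append(
                            dict(start=carrier.start, end=carrier.end,
                                 intensity=parent_left, kind="parent")
                        )
                    sparing = config.tryptic_sparing_fraction
                    crossing_share = carve_total * (1.0 - sparing)
                    internal_share = carve_total * sparing
                    if crossing_share > 0 and not carrier.cterm_is_protein_terminus:
                        # semi-tryptic product: last endogenous site -> next tryptic boundary
                        site_global = carrier.start - 1 + endo_sites[-1]
                        nxt = next(b for b in tryptic_bounds if b > carrier.end)
                        emissions.append(
                            dict(start=site_global + 1, end=nxt,
                                 intensity=crossing_share, kind="crossing")
                        )
                    else:
                        internal_share += crossing_share
                    bounds = [0] + endo_sites + [len(carrier.peptide)]
                    frag_lens = np.diff(bounds)
                    for (b0, b1), flen in zip(zip(bounds[:-1], bounds[1:]), frag_lens):
                        emissions.append(
                            dict(start=carrier.start + b0, end=carrier.start + b1 - 1,
                                 intensity=internal_share * flen / len(carrier.peptide),
                                 kind="internal")
                        )

                for em in emissions:
                    start, end = em["start"], em["end"]
                    pep = seq[start - 1 : end]
                    pre, post = _flanks(seq, start, end)
                    ledger.total_intensity[sample] += em["intensity"]
                    n_term_nontryptic = (
                        start > 1 and pre not in "KR"
                        and not (start == 2 and pre == "M")
                    )
                    c_term_nontryptic = pep[-1] not in "KR" and end < len(seq)
                    is_nontryptic = n_term_nontryptic or c_term_nontryptic
                    if is_nontryptic:
                        ledger.nontryptic_intensity[sample] += em["intensity"]
                        counts = ledger.p1_event_counts[sample]
                        if n_term_nontryptic:
                            counts[pre] = counts.get(pre, 0) + 1
                        if c_term_nontryptic:
                            counts[pep[-1]] = counts.get(pep[-1], 0) + 1
                    if em["kind"] != "parent":
                        ledger.provenance.append(
                            dict(sample_id=sample, protein=rec.accession,
                                 peptide=pep, start=start, end=end, kind=em["kind"],
                                 parent_peptide=carrier.peptide,
                                 parent_start=carrier.start, parent_end=carrier.end)
                        )
                    if rng.random() < config.detectability_dropout:
                        continue
                    noisy = em["intensity"] * float(
                        _lognormal_noise(rng, config.intensity_noise_cv)
                    )
                    observations.append(
                        PeptideObservation(
                            sample_id=sample, peptide=pep,
                            protein_accession=rec.accession,
                            start=start, end=end,
                            preceding_residue=pre, following_residue=post,
                            intensity=noisy,
                        )
                    )

    # adduct feature pairs
    for rec in proteome:
        for spec, carrier in adduct_carriers.get(rec.accession, []):
            base_intensity = abundances[rec.accession]
            pos_in_pep = spec.position - carrier.start + 1
            pre, post = _flanks(rec.sequence, carrier.start, carrier.end)
            for sample in samples:
                theta = spec.occupancy if sample in config.dfp_samples else 0.0
                ledger.occupancies[sample][(spec.accession, spec.position)] = theta
                per_feature = base_intensity / spec.n_features
                ledger.total_intensity[sample] += base_intensity
                for _ in range(spec.n_features):
                    if rng.random() >= config.detectability_dropout:
                        mod_i = theta * per_feature * float(
                            _lognormal_noise(rng, config.intensity_noise_cv)
                        )
                        if mod_i > 0:
                            observations.append(
                                PeptideObservation(
                                    sample_id=sample, peptide=carrier.peptide,
                                    protein_accession=rec.accession,
                                    start=carrier.start, end=carrier.end,
                                    preceding_residue=pre, following_residue=post,
                                    modifications=[
                                        Modification(
                                            pos_in_pep, "DFP", DFP_ADDUCT.delta_mass,
                                            spec.localization_score,
                                        )
                                    ],
                                    intensity=mod_i,
                                )
                            )
                    if rng.random() >= config.detectability_dropout:
                        unmod_i = (1.0 - theta) * per_feature * float(
                            _lognormal_noise(rng, config.intensity_noise_cv)
                        )
                        if unmod_i > 0:
                            observations.append(
                                PeptideObservation(
                                    sample_id=sample, peptide=carrier.peptide,
                                    protein_accession=rec.accession,
                                    start=carrier.start, end=carrier.end,
                                    preceding_residue=pre, following_residue=post,
                                    intensity=unmod_i,
                                )
                            )

    return observations, ledger


# ---------------------------------------------------------------------------
# Reporter matrix
# ---------------------------------------------------------------------------

def generate_reporter_matrix(
    observations: Sequence[PeptideObservation],
    config: SimulationConfig,
    design: Mapping[str, str],
    ledger: Optional[SyntheticLedger] = None,
    sample_id: Optional[str] = None,
) -> tuple[ReporterMatrix, dict[str, float]]:
    """Build a PSM-level reporter matrix from one sample's peptide features.

    ``design`` maps each sample channel to a condition ("treated" or
    "untreated"); proteins selected (seeded) with probability
    ``tmt.fraction_changed`` receive a true log2 fold change of
    ±``tmt.log2fc_magnitude`` in treated channels. Reference channels carry
    the pooled mean of the pre-noise sample-channel values (the reference-pool
    construction). Returns the matrix and the true per-protein log2 fold
    changes; the ledger, when given, records them too.
    """
    tmt = config.tmt
    missing = [c for c in tmt.sample_channels if c not in design]
    if missing:
        raise ValueError(f"design missing channels: {missing}")
    rng = np.random.default_rng(config.seed + 2)

    obs = list(observations)
    if sample_id is not None:
        obs = [o for o in obs if o.sample_id == sample_id]
    elif obs:
        first = sorted({o.sample_id for o in obs})[0]
        obs = [o for o in obs if o.sample_id == first]
    # unique peptide features (modified forms excluded from quant rows)
    base: dict[tuple[str, str], float] = {}
    for o in obs:
        if o.modifications:
            continue
        key = (o.protein_accession, o.peptide)
        base[key] = base.get(key, 0.0) + o.intensity

    proteins = sorted({k[0] for k in base})
    fold_changes: dict[str, float] = {}
    for prot in proteins:
        if rng.random() < tmt.fraction_changed:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fold_changes[prot] = sign * tmt.log2fc_magnitude
        else:
            fold_changes[prot] = 0.0

    rows = []
    psm_counter = 0
    for (prot, pep), intensity in sorted(base.items()):
        lam = max(tmt.psm_per_peptide_mean - 1.0, 0.0)
        n_psm = 1 + int(rng.poisson(lam))
        fc = fold_changes[prot]
        for _ in range(n_psm):
            psm_counter += 1
            row = {"psm_id": f"PSM{psm_counter:07d}", "peptide": pep, "protein": prot}
            prenoise = {}
            for ch in tmt.sample_channels:
                mult = 2.0 ** fc if design[ch] == "treated" else 1.0
                prenoise[ch] = intensity * mult
                row[ch] = prenoise[ch] * float(_lognormal_noise(rng, tmt.reporter_noise_cv))
            pooled = float(np.mean(list(prenoise.values())))
            for ref in tmt.reference_channels:
                row[ref] = pooled * float(_lognormal_noise(rng, tmt.reporter_noise_cv))
            rows.append(row)

    data = pd.DataFrame(rows)
    roles = {ch: "sample" for ch in tmt.sample_channels}
    roles.update({ref: "reference" for ref in tmt.reference_channels})
    if ledger is not None:
        ledger.fold_changes = dict(fold_changes)
    return ReporterMatrix(data, roles), fold_changes


def write_fixture_directory(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Emit a complete synthetic fixture: FASTA + PSM TSV + reporter TSV + ledger TSVs."""
    from pathlib import Path
    from .io_formats import write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(config, fasta_path=out / "proteome.fasta")
    observations, ledger = generate_observations(proteome, config)
    write_table(observations_to_frame(observations), out / "psm_table.tsv")
    design = {
        ch: ("treated" if i % 2 == 0 else "untreated")
        for i, ch in enumerate(config.tmt.sample_channels)
    }
    matrix, fcs = generate_reporter_matrix(observations, config, design, ledger)
    write_table(matrix.data, out / "reporter_matrix.tsv")
    truth = pd.DataFrame(
        [
            {
                "sample_id": s,
                "nontryptic_share": ledger.nontryptic_share(s),
                "total_intensity": ledger.total_intensity[s],
            }
            for s in sorted(ledger.total_intensity)
        ]
    )
    write_table(truth, out / "ledger_shares.tsv")
    write_table(
        pd.DataFrame(
            [{"protein": p, "log2_fc": f} for p, f in sorted(fcs.items())]
        ),
        out / "ledger_fold_changes.tsv",
    )
    if ledger.provenance:
        write_table(ledger.provenance_frame(), out / "ledger_provenance.tsv")
    return {p.name: str(p) for p in out.iterdir()}
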