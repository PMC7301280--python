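"""Synthetic PSM-level TMT data: tryptic peptides of known proteins with
reporter intensities consistent with per-channel protein abundances,
search-score mixtures, decoys and contaminants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..quant import DigestionRule, tryptic_peptides
from .cohort import CohortDesign
from .truth import SyntheticTruth

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# residue weights biased toward K/R so tryptic peptides are frequent
AA_WEIGHTS = np.array([1.0] * 20)
AA_WEIGHTS[[list("ACDEFGHIKLMNPQRSTVWY").index(c) for c in "KR"]] = 2.0
AA_WEIGHTS = AA_WEIGHTS / AA_WEIGHTS.sum()


def generate_protein_sequences(
    n_proteins: int,
    length_range: tuple = (80, 600),
    seed: int = 0,
) -> dict[str, str]:
    """Random protein sequences over the 20-letter alphabet with K/R
    enriched so in-silico digestion yields observable peptides."""
    rng = np.random.default_rng(seed)
    sequences = {}
    for i in range(n_proteins):
        length = int(rng.integers(*length_range))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length, p=AA_WEIGHTS))
        sequences[f"P{i + 1:04d}"] = seq
    return sequences


def generate_psm_table(
    sequences: dict[str, str],
    design: CohortDesign | None = None,
    contamination: float = 0.02,
    decoy: float = 0.05,
    low_score_fraction: float = 0.1,
    n_channels: int = 10,
    psms_per_peptide: tuple = (1, 3),
    reporter_scale: float = 1e4,
    reporter_noise_sd: float = 0.1,
    seed: int = 0,
    rule: DigestionRule = DigestionRule(),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a PSM table from protein sequences.

    Each protein gets log-normal per-channel abundances; every observable
    tryptic peptide spawns 1-3 PSMs whose reporter intensities follow the
    protein's channel profile with multiplicative noise. Search scores are
    a two-component mixture placing ``low_score_fraction`` of target PSMs
    below 15. Precursor intensity is the reporter sum times a per-PSM
    scale factor. Decoy PSMs carry reversed peptides and the reverse flag.
    """
    if not sequences:
        raise ValueError("need at least one protein sequence")
    for frac, name in ((contamination, "contamination"), (decoy, "decoy")):
        if not 0 <= frac < 1:
            raise ValueError(f"{name} fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    channels = [f"reporter_{i + 1}" for i in range(n_channels)]

    abundances = pd.DataFrame(
        rng.lognormal(mean=np.log(1.0), sigma=0.5, size=(len(sequences), n_channels)),
        index=list(sequences),
        columns=channels,
    )

    rows = []
    zero_peptide = []
    psm_id = 0
    for protein, seq in sequences.items():
        peptides = [
            p
            for p in set(tryptic_peptides(seq, rule))
            if rule.min_length <= len(p) <= rule.max_length
        ]
        if not peptides:
            zero_peptide.append(protein)
            continue
        profile = abundances.loc[protein].to_numpy()
        for pep in sorted(peptides):
            efficiency = rng.lognormal(0.0, 0.6)
            n_psm = int(rng.integers(psms_per_peptide[0], psms_per_peptide[1] + 1))
            for _ in range(n_psm):
                noise = rng.lognormal(0.0, reporter_noise_sd, n_channels)
                reporters = reporter_scale * efficiency * profile * noise
                low = rng.random() < low_score_fraction
                score = rng.uniform(5.0, 15.0) if low else rng.uniform(15.0, 120.0)
                precursor = reporters.sum() * rng.lognormal(1.0, 0.3)
                rows.append(
                    _psm_row(psm_id, pep, protein, score, reporters, precursor, False, False)
                )
                psm_id += 1

    n_target = len(rows)
    n_decoy = int(round(decoy / max(1 - decoy, 1e-12) * n_target))
    n_contam = int(round(contamination / max(1 - contamination, 1e-12) * n_target))
    protein_ids = list(sequences)
    for i in range(n_decoy):
        src = protein_ids[int(rng.integers(len(protein_ids)))]
        frags = tryptic_peptides(sequences[src][::-1], rule)
        pep = frags[int(rng.integers(len(frags)))]
        reporters = rng.lognormal(np.log(reporter_scale / 10), 0.5, n_channels)
        rows.append(
            _psm_row(
                psm_id, pep, f"REV_{src}", rng.uniform(5.0, 40.0), reporters,
                reporters.sum() * rng.lognormal(1.0, 0.3), True, False,
            )
        )
        psm_id += 1
    for i in range(n_contam):
        reporters = rng.lognormal(np.log(reporter_scale), 0.5, n_channels)
        rows.append(
            _psm_row(
                psm_id, "KERATINPEPTIDEK", "CON_keratin", rng.uniform(15.0, 120.0),
                reporters, reporters.sum() * rng.lognormal(1.0, 0.3), False, True,
            )
        )
        psm_id += 1

    table = pd.DataFrame(rows)
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    truth = SyntheticTruth(
        seed=seed,
        protein_abundances=abundances,
        zero_peptide_proteins=zero_peptide,
        low_score_fraction=low_score_fraction,
    )
    return table, truth


def _psm_row(psm_id, peptide, protein, score, reporters, precursor, is_reverse, is_contaminant):
    row = {
        "psm_id": f"psm_{psm_id:06d}",
        "peptide_sequence": peptide,
        "protein_group_id": protein,
        "is_unique_peptide": True,
        "search_score": float(score),
        "precursor_intensity": float(precursor),
        "is_reverse": bool(is_reverse),
        "is_contaminant": bool(is_contaminant),
        "run_id": "run_1",
    }
    for i, value in enumerate(reporters):
        row[f"reporter_{i + 1}"] = float(value)
    return row
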