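"""Shared fixtures: random peptidoform factories, an independent element-mass
oracle, and a session-scoped repeated-simulation study reused by the slower
statistical tests."""

from __future__ import annotations

import numpy as np
import pytest

import phosflr as pf
from phosflr.synthetic_data import SimulationConfig, simulate_dataset

# ---------------------------------------------------------------------------
# Independent element-mass oracle (deliberately separate from the package's
# residue-mass table: everything here is summed from elemental formulas).

ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}
ORACLE_PROTON = 1.00727646688

AA_FORMULA = {  # residue (amino acid minus water) elemental compositions
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}
MOD_FORMULA = {
    "Phospho": "HPO3",
    "Oxidation": "O",
    "Carbamidomethyl": "C2H3NO",
    "Acetyl": "C2H2O",
}
LOSS_FORMULA = {
    "": None, "o": "H2O", "n": "NH3", "p": "H3PO4",
    "op": "H2O,H3PO4", "np": "NH3,H3PO4", "2p": "H3PO4,H3PO4",
    "o2p": "H2O,H3PO4,H3PO4", "n2p": "NH3,H3PO4,H3PO4",
}

import functools
import re as _re


@functools.lru_cache(maxsize=None)
def formula_mass(formula: str) -> float:
    total = 0.0
    for part in formula.split(","):
        for el, count in _re.findall(r"([A-Z][a-z]?)(\d*)", part):
            if el:
                total += ELEMENT_MASS[el] * (int(count) if count else 1)
    return total


def oracle_fragment_mz(p: pf.Peptidoform, series: str, loss: str, k: int,
                       fragment_charge: int) -> float:
    """Brute-force fragment m/z from elemental formulas."""
    L = len(p.sequence)
    residues = p.sequence[:k] if series == "b" else p.sequence[L - k:]
    mass = sum(formula_mass(AA_FORMULA[aa]) for aa in residues)
    for pos, name in p.mods:
        idx = pos if pos > 0 else 1
        in_frag = idx <= k if series == "b" else idx > L - k
        if in_frag:
            mass += formula_mass(MOD_FORMULA[name])
    if series == "y":
        mass += formula_mass("H2O")
    if LOSS_FORMULA[loss]:
        mass -= formula_mass(LOSS_FORMULA[loss])
    return (mass + fragment_charge * ORACLE_PROTON) / fragment_charge


def oracle_precursor_mz(p: pf.Peptidoform) -> float:
    mass = sum(formula_mass(AA_FORMULA[aa]) for aa in p.sequence)
    mass += sum(formula_mass(MOD_FORMULA[name]) for _, name in p.mods)
    mass += formula_mass("H2O")
    return (mass + p.charge * ORACLE_PROTON) / p.charge


# ---------------------------------------------------------------------------
# Random peptidoform factory

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def make_random_peptidoform(
    rng: np.random.Generator,
    min_length: int = 6,
    max_length: int = 20,
    n_phospho: int | None = None,
    with_other_mods: bool = True,
) -> pf.Peptidoform:
    while True:
        length = int(rng.integers(min_length, max_length + 1))
        seq = "".join(RESIDUES[i] for i in rng.integers(0, len(RESIDUES), length))
        sites = [i for i, aa in enumerate(seq, 1) if aa in "STY"]
        want = n_phospho if n_phospho is not None else int(rng.integers(0, 3))
        if len(sites) >= want:
            break
    mods = []
    if want:
        for pos in rng.choice(sites, size=want, replace=False):
            mods.append((int(pos), "Phospho"))
    if with_other_mods:
        taken = {m[0] for m in mods}
        for i, aa in enumerate(seq, 1):
            if i in taken:
                continue
            if aa == "M" and rng.random() < 0.2:
                mods.append((i, "Oxidation"))
            elif aa == "C" and rng.random() < 0.5:
                mods.append((i, "Carbamidomethyl"))
        if rng.random() < 0.1 and 0 not in taken:
            mods.append((0, "Acetyl"))
    charge = int(rng.integers(1, 4))
    return pf.Peptidoform(seq, tuple(mods), charge)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230420)


@pytest.fixture
def peptidoform_factory(rng):
    def factory(**kwargs):
        return make_random_peptidoform(rng, **kwargs)

    return factory


# ---------------------------------------------------------------------------
# Session-scoped repeated-simulation study (shared by calibration, recovery,
# and separation tests so the 10 runs happen once).

N_STUDY_SEEDS = 10
STUDY_N_PEPTIDES = 500
THRESHOLD_GRID = np.linspace(0.0, 0.5, 51)


@pytest.fixture(scope="session")
def simulation_study():
    """Run the default-noise benchmark over 10 seeds and keep the curves."""
    from phosflr.flr_engine import curve_at_thresholds

    runs = []
    predictor = pf.BaselinePredictor()
    for seed in range(N_STUDY_SEEDS):
        cfg = SimulationConfig(n_peptides=STUDY_N_PEPTIDES, seed=seed)
        ds = simulate_dataset(cfg)
        records, db = pf.analyze_dataset(
            ds.spectra, ds.identifications, predictor, method=1, seed=seed
        )
        records = [r for r in records if not r.unscorable]
        truth = ds.truth_by_id
        curve = pf.flr_curve(records, db.N_decoy, db.N_target, ground_truth=truth)
        est = curve_at_thresholds(curve, THRESHOLD_GRID, "flr_estimated")
        real = curve_at_thresholds(curve, THRESHOLD_GRID, "flr_real")
        try:
            thr, n_acc, accepted = pf.threshold_at_flr(curve, 0.01, records)
            n_true_accepted = sum(
                1
                for r in accepted
                if not r.is_decoy and r.best_candidate.mods == truth[r.spectrum_id].mods
            )
            recovery = n_true_accepted / len(records)
        except ValueError:
            recovery = 0.0
        runs.append(
            {
                "seed": seed,
                "records": records,
                "truth": truth,
                "curve": curve,
                "est_at_grid": est,
                "real_at_grid": real,
                "recovery": recovery,
                "N_decoy": db.N_decoy,
                "N_target": db.N_target,
            }
        )
    return runs
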