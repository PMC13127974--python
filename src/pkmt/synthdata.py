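"""Synthetic compound datasets with the statistical structure of small-molecule PK tables.

The generator emulates what a merged clearance / volume-of-distribution
compound table looks like: positive, right-skewed human CL and VDss that
share a latent correlation on the log scale, allometrically correlated
rat/dog/monkey values, fraction-unbound and pKa covariates carrying signal,
and a fraction of compounds missing one of the two human endpoints.

The two task latents are

    t_CL = sqrt(rho) * s + sqrt(1 - rho) * z1 + delta * z_mol
    t_VD = sqrt(rho) * s + sqrt(1 - rho) * z2 + delta * z_mol

with s, z1, z2 iid standard normal, z_mol the standardized heavy-atom count
of the generated molecule, rho the shared-latent correlation and delta the
weight of the molecular-size signal.  Human values are
log10 CL = mu_logCL + sigma_logCL * t_CL (likewise VD).

Truth latents are kept in a side table for diagnostics only; model-fitting
code never sees them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# free valences for the heavy atoms used in fragment assembly
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}
_CHAIN_ATOMS = ["C", "C", "C", "N", "O", "S", "F", "Cl"]  # C-rich, halogens terminal
_RING_FRAGMENTS = [
    "C1CCCCC1",  # cyclohexane
    "c1ccccc1",  # benzene
    "C1CCNCC1",  # piperidine
    "C1CCOC1",   # tetrahydrofuran
    "c1ccncc1",  # pyridine
    "C1CCNC1",   # pyrrolidine
]

CSV_COLUMNS = [
    "name", "smiles",
    "human_CL_mL_min_kg", "human_VDss_L_kg",
    "rat_CL_mL_min_kg", "rat_VDss_L_kg",
    "dog_CL_mL_min_kg", "dog_VDss_L_kg",
    "monkey_CL_mL_min_kg", "monkey_VDss_L_kg",
    "human_fup", "rat_fup", "dog_fup", "monkey_fup",
    "pKa_Acid", "pKa_base",
]

# species-level allometric anchors: log10(value) = alpha + kappa * t_task + noise
_SPECIES_CL = {"rat": (0.95, 0.40), "dog": (0.75, 0.42), "monkey": (0.85, 0.40)}
_SPECIES_VD = {"rat": (0.00, 0.42), "dog": (-0.05, 0.40), "monkey": (-0.02, 0.41)}
_FUP_SLOPE = -0.8  # high-VD (tissue-avid) compounds tend to be highly bound
_FUP_NOISE = 0.5


@dataclass
class SynthConfig:
    """Parameters of the synthetic PK data generating process.

    Defaults put ~95% of human CL below 20 mL/min/kg and ~95% of VDss below
    5 L/kg, so the physiological-range filter removes only a small tail.
    """

    n_compounds: int = 700
    rho_shared: float = 0.6
    mu_logCL: float = 0.5       # log10 mL/min/kg; median ~3.2
    sigma_logCL: float = 0.45
    mu_logVD: float = -0.15     # log10 L/kg; median ~0.71
    sigma_logVD: float = 0.45
    animal_noise_sd: float = 0.35
    mol_signal_weight: float = 0.3
    missing_frac_cl: float = 0.10
    missing_frac_vd: float = 0.15
    max_heavy_atoms: int = 30
    seed: int = 0
    species_cl: dict = field(default_factory=lambda: dict(_SPECIES_CL))
    species_vd: dict = field(default_factory=lambda: dict(_SPECIES_VD))

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not 0.0 <= self.rho_shared <= 1.0:
            raise ValueError("rho_shared must lie in [0, 1]")
        if self.sigma_logCL <= 0 or self.sigma_logVD <= 0:
            raise ValueError("sigmas must be positive")
        for f in (self.missing_frac_cl, self.missing_frac_vd):
            if not 0.0 <= f < 1.0:
                raise ValueError("missing fractions must lie in [0, 1)")
        if self.animal_noise_sd < 0:
            raise ValueError("animal_noise_sd must be >= 0")
        if self.max_heavy_atoms < 2:
            raise ValueError("max_heavy_atoms must be >= 2")


@dataclass
class SyntheticDataset:
    """Generated compound table plus the hidden truth latents."""

    table: pd.DataFrame          # CSV_COLUMNS layout; NaN = missing
    truth: pd.DataFrame          # columns: s, t_CL, t_VD, z_mol
    config: SynthConfig


def _free_valence(mol: Chem.RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    cap = _VALENCE[atom.GetSymbol()]
    used = sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds())
    if atom.GetIsAromatic():
        used += 1  # aromatic ring accounting: one implicit extra
    return cap - used


def _attachment_points(mol: Chem.RWMol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if _free_valence(mol, a.GetIdx()) >= 1]


def _random_molecule(rng: np.random.Generator, max_heavy_atoms: int) -> str:
    """Assemble one molecule from chain atoms and ring fragments, valence-safe."""
    target = int(rng.integers(3, max_heavy_atoms + 1))
    # seed fragment: ring or single carbon
    if target >= 6 and rng.random() < 0.5:
        mol = Chem.RWMol(Chem.MolFromSmiles(_RING_FRAGMENTS[rng.integers(len(_RING_FRAGMENTS))]))
    else:
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom("C"))
    while mol.GetNumAtoms() < target:
        points = _attachment_points(mol)
        if not points:
            break
        at = int(points[rng.integers(len(points))])
        room = target - mol.GetNumAtoms()
        if room >= 6 and rng.random() < 0.25:
            frag = Chem.MolFromSmiles(_RING_FRAGMENTS[rng.integers(len(_RING_FRAGMENTS))])
            offset = mol.GetNumAtoms()
            mol.InsertMol(frag)
            mol.AddBond(at, offset, Chem.BondType.SINGLE)
        else:
            sym = _CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))]
            new_idx = mol.AddAtom(Chem.Atom(sym))
            mol.AddBond(at, new_idx, Chem.BondType.SINGLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        # rare sanitize failure (odd aromatic substitution): fall back to propane
        return "C" + "C" * min(2, max_heavy_atoms - 1)
    return Chem.MolToSmiles(out)


def generate_molecules(n: int, seed: int, max_heavy_atoms: int = 30) -> list[str]:
    """Generate ``n`` valid SMILES by random fragment assembly.

    Deterministic for a given seed; duplicates are permitted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if max_heavy_atoms < 2:
        raise ValueError("max_heavy_atoms must be >= 2")
    rng = np.random.default_rng(seed)
    return [_random_molecule(rng, max_heavy_atoms) for _ in range(n)]


def latent_pk_model(
    s: float, z1: float, z2: float, z_mol: float, cfg: SynthConfig
) -> tuple[float, float, float, float]:
    """Map shared / task-specific / molecular latents to log10 CL and VDss.

    Returns (logCL, logVD, t_CL, t_VD).
    """
    cfg.validate()
    root_rho = math.sqrt(cfg.rho_shared)
    root_ind = math.sqrt(1.0 - cfg.rho_shared)
    delta = cfg.mol_signal_weight
    t_cl = root_rho * s + root_ind * z1 + delta * z_mol
    t_vd = root_rho * s + root_ind * z2 + delta * z_mol
    log_cl = cfg.mu_logCL + cfg.sigma_logCL * t_cl
    log_vd = cfg.mu_logVD + cfg.sigma_logVD * t_vd
    return log_cl, log_vd, t_cl, t_vd


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(20):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def generate_pk_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Draw a full synthetic compound table under ``cfg``.

    Human values come from the shared-latent model; animal values are
    log10-allometric in the corresponding task latent with species noise;
    fup is a logistic transform of the distribution latent; pKa values are
    truncated normals.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    n = cfg.n_compounds
    rng = np.random.default_rng(cfg.seed)

    smiles = generate_molecules(n, seed=int(rng.integers(2**31 - 1)),
                                max_heavy_atoms=cfg.max_heavy_atoms)
    heavy = np.array([Chem.MolFromSmiles(s).GetNumHeavyAtoms() for s in smiles], float)
    sd_h = heavy.std()
    z_mol = (heavy - heavy.mean()) / (sd_h if sd_h > 0 else 1.0)

    s = rng.normal(size=n)
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    root_rho = math.sqrt(cfg.rho_shared)
    root_ind = math.sqrt(1.0 - cfg.rho_shared)
    t_cl = root_rho * s + root_ind * z1 + cfg.mol_signal_weight * z_mol
    t_vd = root_rho * s + root_ind * z2 + cfg.mol_signal_weight * z_mol
    log_cl = cfg.mu_logCL + cfg.sigma_logCL * t_cl
    log_vd = cfg.mu_logVD + cfg.sigma_logVD * t_vd

    data: dict[str, np.ndarray | list] = {
        "name": [f"SYN-{i:05d}" for i in range(n)],
        "smiles": smiles,
        "human_CL_mL_min_kg": 10.0 ** log_cl,
        "human_VDss_L_kg": 10.0 ** log_vd,
    }
    for sp in ("rat", "dog", "monkey"):
        a_cl, k_cl = cfg.species_cl[sp]
        a_vd, k_vd = cfg.species_vd[sp]
        data[f"{sp}_CL_mL_min_kg"] = 10.0 ** (
            a_cl + k_cl * t_cl + rng.normal(0, cfg.animal_noise_sd, n))
        data[f"{sp}_VDss_L_kg"] = 10.0 ** (
            a_vd + k_vd * t_vd + rng.normal(0, cfg.animal_noise_sd, n))
    for sp in ("human", "rat", "dog", "monkey"):
        lin = _FUP_SLOPE * t_vd + rng.normal(0, _FUP_NOISE, n)
        data[f"{sp}_fup"] = 1.0 / (1.0 + np.exp(-lin))
    data["pKa_Acid"] = _truncnorm(rng, 5.0, 2.0, 0.0, 14.0, n)
    data["pKa_base"] = _truncnorm(rng, 7.0, 2.0, 0.0, 14.0, n)

    # reorder animal columns to the canonical layout
    table = pd.DataFrame(data)[CSV_COLUMNS]

    miss_cl = rng.random(n) < cfg.missing_frac_cl
    miss_vd = rng.random(n) < cfg.missing_frac_vd
    both = miss_cl & miss_vd  # never drop both endpoints
    miss_vd[both] = False
    table.loc[miss_cl, "human_CL_mL_min_kg"] = np.nan
    table.loc[miss_vd, "human_VDss_L_kg"] = np.nan

    truth = pd.DataFrame({"s": s, "t_CL": t_cl, "t_VD": t_vd, "z_mol": z_mol})
    return SyntheticDataset(table=table, truth=truth, config=cfg)


def write_dataset_csv(dataset: SyntheticDataset, path: str) -> None:
    """Write the compound table (one row per compound, empty cell = missing)."""
    dataset.table.to_csv(path, index=False)
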