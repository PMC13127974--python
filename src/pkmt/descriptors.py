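"""Molecular inputs for the embedders: rendered 2-D depictions and a fixed
561-length descriptor vector.

The descriptor vector concatenates five global descriptors (molecular
weight, Crippen logP, H-bond donor/acceptor counts, TPSA), a 256-bit
Morgan fingerprint (radius 2), and a 300-dimensional dense block of hashed
radius-0/1 circular-substructure counts.  The hashed block is a
deterministic, download-free stand-in for pretrained substructure
embeddings: each substructure identifier is feature-hashed into one of 300
signed slots, preserving vector length and per-SMILES determinism.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Draw, rdFingerprintGenerator
from rdkit.Chem.Draw import rdMolDraw2D

GLOBAL_DESCRIPTOR_NAMES = ["mol_weight", "logp", "hbd", "hba", "tpsa"]
N_FP_BITS = 256
N_SUBSTRUCT = 300
DESCRIPTOR_LENGTH = len(GLOBAL_DESCRIPTOR_NAMES) + N_FP_BITS + N_SUBSTRUCT

DESCRIPTOR_NAMES = (
    GLOBAL_DESCRIPTOR_NAMES
    + [f"fp_{i}" for i in range(N_FP_BITS)]
    + [f"sub_{i}" for i in range(N_SUBSTRUCT)]
)

_morgan256 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=N_FP_BITS)
_morgan_sub = rdFingerprintGenerator.GetMorganGenerator(radius=1)


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass
class MolecularImage:
    pixels: np.ndarray  # (size, size, 3) float in [0, 1]
    smiles: str


def render_molecule_image(smiles: str, size: int = 224) -> MolecularImage:
    """Deterministic 2-D depiction on white background, size x size x 3."""
    mol = _parse(smiles)
    drawer = rdMolDraw2D.MolDraw2DCairo(size, size)
    rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
    drawer.FinishDrawing()
    png = drawer.GetDrawingText()
    from PIL import Image

    img = Image.open(io.BytesIO(png)).convert("RGB")
    arr = np.asarray(img, dtype=np.float64) / 255.0
    return MolecularImage(pixels=arr, smiles=smiles)


def render_images(smiles_list, size: int = 224) -> np.ndarray:
    """Stack of depictions, shape (n, size, size, 3)."""
    return np.stack([render_molecule_image(s, size).pixels for s in smiles_list])


def assemble_descriptor_vector(smiles: str) -> np.ndarray:
    """Fixed-length (561) numeric vector for one molecule."""
    mol = _parse(smiles)
    glob = np.array([
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        Descriptors.NumHDonors(mol),
        Descriptors.NumHAcceptors(mol),
        Descriptors.TPSA(mol),
    ])
    fp = np.zeros(N_FP_BITS)
    bv = _morgan256.GetFingerprint(mol)
    fp[list(bv.GetOnBits())] = 1.0
    sub = np.zeros(N_SUBSTRUCT)
    counts = _morgan_sub.GetSparseCountFingerprint(mol).GetNonzeroElements()
    for ident, count in counts.items():
        slot = ident % N_SUBSTRUCT
        sign = 1.0 if (ident >> 16) & 1 else -1.0
        sub[slot] += sign * count
    return np.concatenate([glob, fp, sub])


def descriptor_matrix(smiles_list) -> np.ndarray:
    return np.stack([assemble_descriptor_vector(s) for s in smiles_list])
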