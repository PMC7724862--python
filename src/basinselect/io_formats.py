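"""On-disk representations for decoy ensembles, basin assignments and reports.

A decoy ensemble is carried as a tab-separated score table with one row per
decoy: ``decoy_id``, ``energy``, optionally ``rmsd_native`` (true lRMSD to the
known native, in Å), and the 20 named scoring-feature columns of the
:class:`FeatureSchema`.  Cα coordinates are optional and may come from PDB
files or a long-format TSV; the downstream pipeline only ever consumes
pairwise distances and energies, so every stage also runs from a precomputed
distance matrix with no structure files at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class BasinSelectError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BasinSelectError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(BasinSelectError):
    """Input data violates a documented invariant."""


class ConfigurationError(BasinSelectError):
    """An option combination cannot be resolved."""


DEFAULT_KNOWLEDGE_BASED = ("RW", "RWplus", "dDFIRE")
DEFAULT_ROSETTA_TERMS = (
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_sol", "lk_ball_wtd",
    "fa_intra_rep", "fa_elec", "pro_close", "hbond_sr_bb", "hbond_lr_bb",
    "hbond_bb_sc", "hbond_sc", "rama_prepro", "omega", "p_aa_pp",
    "fa_dun", "yhh_planarity",
)

#: Recognised distance semantics for an ensemble.
DISTANCE_SPECS = ("euclidean", "common-frame-rmsd", "matrix")


@dataclass(frozen=True)
class FeatureSchema:
    """Names of the per-decoy scoring features (3 knowledge-based potentials
    plus 17 all-atom energy terms)."""

    knowledge_based: tuple[str, ...] = DEFAULT_KNOWLEDGE_BASED
    rosetta_terms: tuple[str, ...] = DEFAULT_ROSETTA_TERMS

    @property
    def names(self) -> tuple[str, ...]:
        return self.knowledge_based + self.rosetta_terms

    @property
    def total(self) -> int:
        return len(self.knowledge_based) + len(self.rosetta_terms)


DEFAULT_SCHEMA = FeatureSchema()


@dataclass
class Decoy:
    """One sampled tertiary structure: id, landscape fitness (energy), the
    scoring-feature vector, and optionally true lRMSD-to-native and Cα
    coordinates."""

    decoy_id: str
    energy: float
    features: np.ndarray
    rmsd_native: Optional[float] = None
    coords: Optional[np.ndarray] = None  # (n_atoms, 3), Å


@dataclass
class Ensemble:
    """All decoys for one target (the set Ω), stored column-wise.

    ``decoy_ids`` is the per-row identifier list; ``energies`` the fitness
    vector f; ``features`` the (|Ω|, 20) score matrix; ``rmsd_native`` the
    optional true-distance column; ``coords`` an optional (|Ω|, n_atoms, 3)
    array; ``dist_matrix`` an optional precomputed symmetric matrix.
    """

    target_id: str
    decoy_ids: list[str]
    energies: np.ndarray
    features: np.ndarray
    schema: FeatureSchema = DEFAULT_SCHEMA
    rmsd_native: Optional[np.ndarray] = None
    coords: Optional[np.ndarray] = None
    distance_spec: str = "euclidean"
    dist_matrix: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        if len(self.decoy_ids) != len(set(self.decoy_ids)):
            raise ValidationError(f"duplicate decoy_id in target {self.target_id!r}")
        if self.features.shape != (self.size, self.schema.total):
            raise ValidationError(
                f"feature matrix shape {self.features.shape} does not match "
                f"({self.size}, {self.schema.total})")
        if self.rmsd_native is not None:
            self.rmsd_native = np.asarray(self.rmsd_native, dtype=float)
            if np.any(self.rmsd_native < 0):
                raise ValidationError("rmsd_native must be non-negative")
        if self.distance_spec not in DISTANCE_SPECS:
            raise ConfigurationError(f"unknown distance_spec {self.distance_spec!r}")
        if self.distance_spec == "matrix":
            if self.dist_matrix is None:
                raise ValidationError("distance_spec='matrix' requires dist_matrix")
            m = np.asarray(self.dist_matrix, dtype=float)
            if m.shape != (self.size, self.size):
                raise ValidationError("dist_matrix shape mismatch")
            if np.any(m < 0) or not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
                raise ValidationError(
                    "dist_matrix must be symmetric, non-negative, zero-diagonal")
            self.dist_matrix = m

    @property
    def size(self) -> int:
        return len(self.decoy_ids)

    @property
    def native_known(self) -> bool:
        return self.rmsd_native is not None

    @property
    def min_dist(self) -> Optional[float]:
        """Minimum true lRMSD to the native over the ensemble, if known."""
        if self.rmsd_native is None:
            return None
        return float(np.min(self.rmsd_native))

    def decoy(self, i: int) -> Decoy:
        return Decoy(
            decoy_id=self.decoy_ids[i],
            energy=float(self.energies[i]),
            features=self.features[i],
            rmsd_native=None if self.rmsd_native is None else float(self.rmsd_native[i]),
            coords=None if self.coords is None else self.coords[i],
        )

    @classmethod
    def from_decoys(cls, target_id: str, decoys: Sequence[Decoy],
                    schema: FeatureSchema = DEFAULT_SCHEMA,
                    distance_spec: str = "euclidean") -> "Ensemble":
        if len(decoys) < 2:
            raise ValidationError("an ensemble needs at least 2 decoys")
        rmsd = None
        if all(d.rmsd_native is not None for d in decoys):
            rmsd = np.array([d.rmsd_native for d in decoys], dtype=float)
        coords = None
        if all(d.coords is not None for d in decoys):
            lens = {np.asarray(d.coords).shape for d in decoys}
            if len(lens) != 1:
                raise ValidationError("decoys with coords must have equal atom counts")
            coords = np.stack([np.asarray(d.coords, dtype=float) for d in decoys])
        return cls(
            target_id=target_id,
            decoy_ids=[d.decoy_id for d in decoys],
            energies=np.array([d.energy for d in decoys], dtype=float),
            features=np.vstack([np.asarray(d.features, dtype=float) for d in decoys]),
            schema=schema,
            rmsd_native=rmsd,
            coords=coords,
            distance_spec=distance_spec,
        )


# ---------------------------------------------------------------------------
# decoy score tables


def read_decoy_table(path, schema: FeatureSchema = DEFAULT_SCHEMA,
                     target_id: Optional[str] = None) -> Ensemble:
    """Read a tab-separated decoy score table into an :class:`Ensemble`.

    Columns are matched by name (order-independent, case-sensitive).
    ``decoy_id``, ``energy`` and every schema feature column are required;
    ``rmsd_native`` is optional.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"decoy_id": str})
    for col in ("decoy_id", "energy", *schema.names):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    numeric_cols = ["energy", *schema.names]
    if "rmsd_native" in df.columns:
        numeric_cols.append("rmsd_native")
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        elif converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
        else:
            df[col] = converted
            continue
        raise FormatError(f"{path.name}: non-numeric value in column {col!r}, line {row}")
    ids = df["decoy_id"].tolist()
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{path.name}: duplicate decoy_id")
    return Ensemble(
        target_id=target_id or path.stem,
        decoy_ids=ids,
        energies=df["energy"].to_numpy(float),
        features=df[list(schema.names)].to_numpy(float),
        schema=schema,
        rmsd_native=df["rmsd_native"].to_numpy(float) if "rmsd_native" in df.columns else None,
    )


def write_decoy_table(ensemble: Ensemble, path) -> None:
    """Write an ensemble as the TSV dialect read by :func:`read_decoy_table`."""
    cols: dict[str, object] = {"decoy_id": ensemble.decoy_ids, "energy": ensemble.energies}
    if ensemble.rmsd_native is not None:
        cols["rmsd_native"] = ensemble.rmsd_native
    for j, name in enumerate(ensemble.schema.names):
        cols[name] = ensemble.features[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# coordinates


def read_ca_coordinates(paths: Sequence, ensemble: Ensemble) -> Ensemble:
    """Attach Cα coordinates parsed from PDB files to matching decoys.

    Each file's stem must equal a decoy_id. Only the first model and first
    altloc are used; atoms are taken in residue order. All decoys must end up
    with the same atom count.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    by_id = {Path(p).stem: Path(p) for p in paths}
    missing = [d for d in ensemble.decoy_ids if d not in by_id]
    if missing:
        raise ValidationError(f"no coordinate file for decoy_id {missing[0]!r}")
    coords = []
    n_atoms = None
    for decoy_id in ensemble.decoy_ids:
        structure = parser.get_structure(decoy_id, str(by_id[decoy_id]))
        model = next(structure.get_models())
        xyz = []
        for chain in model:
            for residue in chain:
                if "CA" in residue:
                    atom = residue["CA"]
                    if atom.is_disordered():
                        atom = atom.disordered_get_list()[0]
                    xyz.append(atom.get_coord())
        if not xyz:
            raise ValidationError(f"{by_id[decoy_id].name}: no CA atoms")
        if n_atoms is None:
            n_atoms = len(xyz)
        elif len(xyz) != n_atoms:
            raise ValidationError(
                f"decoy {decoy_id!r} has {len(xyz)} CA atoms, expected {n_atoms}")
        coords.append(np.asarray(xyz, dtype=float))
    ensemble.coords = np.stack(coords)
    return ensemble


def write_ca_pdb(coords: np.ndarray, path) -> None:
    """Write a (n_atoms, 3) Cα trace as a minimal PDB file (poly-alanine)."""
    lines = []
    for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float), start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_coordinate_table(path, ensemble: Ensemble) -> Ensemble:
    """Attach coordinates from a long-format TSV (decoy_id, atom_index, x, y, z)."""
    df = pd.read_csv(path, sep="\t", dtype={"decoy_id": str})
    for col in ("decoy_id", "atom_index", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    grouped = {k: g.sort_values("atom_index")[["x", "y", "z"]].to_numpy(float)
               for k, g in df.groupby("decoy_id")}
    missing = [d for d in ensemble.decoy_ids if d not in grouped]
    if missing:
        raise ValidationError(f"no coordinates for decoy_id {missing[0]!r}")
    counts = {grouped[d].shape[0] for d in ensemble.decoy_ids}
    if len(counts) != 1:
        raise ValidationError(f"unequal atom counts across decoys: {sorted(counts)}")
    ensemble.coords = np.stack([grouped[d] for d in ensemble.decoy_ids])
    return ensemble


def write_coordinate_table(ensemble: Ensemble, path) -> None:
    if ensemble.coords is None:
        raise ValidationError("ensemble has no coordinates")
    n, m, _ = ensemble.coords.shape
    df = pd.DataFrame({
        "decoy_id": np.repeat(ensemble.decoy_ids, m),
        "atom_index": np.tile(np.arange(m), n),
        "x": ensemble.coords[:, :, 0].ravel(),
        "y": ensemble.coords[:, :, 1].ravel(),
        "z": ensemble.coords[:, :, 2].ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# basin assignments


def write_basin_assignment(decomp, ensemble: Ensemble, path) -> None:
    """Write a basin decomposition as TSV: decoy_id, basin_id, is_focal_minimum."""
    focal = {b.focal_minimum for b in decomp.basins}
    df = pd.DataFrame({
        "decoy_id": ensemble.decoy_ids,
        "basin_id": decomp.assignment,
        "is_focal_minimum": [int(i in focal) for i in range(ensemble.size)],
    })
    df.to_csv(path, sep="\t", index=False)


def read_basin_assignment(path, ensemble: Ensemble):
    """Read a basin-assignment TSV back into a BasinDecomposition."""
    from .landscape import Basin, BasinDecomposition

    df = pd.read_csv(path, sep="\t", dtype={"decoy_id": str})
    for col in ("decoy_id", "basin_id", "is_focal_minimum"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    index = {d: i for i, d in enumerate(ensemble.decoy_ids)}
    unknown = [d for d in df["decoy_id"] if d not in index]
    if unknown:
        raise ValidationError(f"unknown decoy_id {unknown[0]!r}")
    if len(df) != ensemble.size:
        raise ValidationError("assignment row count does not match ensemble size")
    assignment = np.empty(ensemble.size, dtype=int)
    assignment[[index[d] for d in df["decoy_id"]]] = df["basin_id"].to_numpy(int)
    basins = []
    for bid in sorted(set(assignment.tolist())):
        members = np.flatnonzero(assignment == bid)
        focal_rows = df[(df["basin_id"] == bid) & (df["is_focal_minimum"] == 1)]
        if len(focal_rows) != 1:
            raise ValidationError(f"basin {bid} must have exactly one focal minimum")
        focal = index[focal_rows["decoy_id"].iloc[0]]
        basins.append(Basin(
            basin_id=int(bid), focal_minimum=int(focal), members=members,
            focal_energy=float(ensemble.energies[focal])))
    return BasinDecomposition(basins=basins, assignment=assignment)


# ---------------------------------------------------------------------------
# reports


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    return obj


def write_report(result, path) -> None:
    """Write a selection result / evaluation structure as deterministic JSON."""
    payload = _to_jsonable(result)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path):
    with open(path) as fh:
        return json.load(fh)
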