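"""Ligand library preparation and chemotype characterization.

Screening libraries built from public bioactivity data often store a
single arbitrary enantiomer for compounds whose activity was measured on
a racemic sample.  The preparation pipeline here mirrors the racemic
convention: structures are flattened to their 2D constitution, molecules
with at least one stereocenter are flagged racemic, the stereoisomer
count is recorded, and constitution duplicates (the same compound
deposited in two enantiomeric states) are merged so each compound is
counted once in downstream screening statistics.

Known-ligand libraries are additionally clustered into chemotype
families (at most four named clusters A–D plus "other") by complete-
linkage hierarchical clustering on Tanimoto dissimilarity of Morgan
fingerprints, with the medoid of each cluster reported as its
representative.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, DataStructs, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "LigandRecord",
    "LigandLibrary",
    "ChemotypeClustering",
    "LibraryError",
    "load_library",
    "racemize_library",
    "deduplicate",
    "cluster_chemotypes",
]

MAX_ENANTIOMER_MULTIPLICITY = 2**10


class LibraryError(ValueError):
    """Raised for unrecoverable library-preparation problems."""


@dataclass
class LigandRecord:
    ligand_id: str
    mol: Chem.Mol
    constitution_key: str  # canonical achiral structure key
    n_stereocenters: int
    racemic_flag: bool
    enantiomer_multiplicity: int
    class_label: str = "active"  # active | decoy
    pharmacology: str = "unknown"  # agonist | inhibitor | unknown
    chemotype: str = "unassigned"


@dataclass
class LigandLibrary:
    records: list[LigandRecord]
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, ligand_id: str) -> LigandRecord:
        for rec in self.records:
            if rec.ligand_id == ligand_id:
                return rec
        raise KeyError(ligand_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand_id": [r.ligand_id for r in self.records],
                "constitution_key": [r.constitution_key for r in self.records],
                "n_stereocenters": [r.n_stereocenters for r in self.records],
                "racemic_flag": [r.racemic_flag for r in self.records],
                "multiplicity": [r.enantiomer_multiplicity for r in self.records],
                "class_label": [r.class_label for r in self.records],
                "pharmacology": [r.pharmacology for r in self.records],
                "chemotype": [r.chemotype for r in self.records],
            }
        )


@dataclass
class ChemotypeClustering:
    labels: dict[str, str]  # ligand_id -> cluster label (A..D or "other")
    centers: dict[str, str]  # cluster label -> medoid ligand_id
    linkage_height: float
    max_clusters: int
    linkage_matrix: np.ndarray | None = None
    annotations: dict[str, str] = field(default_factory=dict)  # label -> e.g. X-ray ligand code

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.labels.values():
            out[label] = out.get(label, 0) + 1
        return out

    def annotate_xray_ligand(self, ligand_id: str, three_letter_code: str) -> None:
        """Tag the cluster containing a co-crystal ligand with its 3-letter code."""
        if ligand_id not in self.labels:
            raise KeyError(ligand_id)
        self.annotations[self.labels[ligand_id]] = three_letter_code


def _count_stereocenters(mol: Chem.Mol) -> int:
    # Potential tetrahedral stereocenters, assigned or not: after flattening
    # to 2D constitution these are exactly the centers a racemic flag covers.
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return len(centers)


def _constitution_key(mol: Chem.Mol) -> str:
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return Chem.MolToSmiles(flat)


def _make_record(mol: Chem.Mol, ligand_id: str) -> LigandRecord:
    n_stereo = _count_stereocenters(mol)
    return LigandRecord(
        ligand_id=ligand_id,
        mol=mol,
        constitution_key=_constitution_key(mol),
        n_stereocenters=n_stereo,
        racemic_flag=n_stereo >= 1,
        enantiomer_multiplicity=1,
    )


def _apply_labels(records: list[LigandRecord], labels: pd.DataFrame) -> None:
    by_id = labels.set_index("ligand_id")
    for rec in records:
        if rec.ligand_id in by_id.index:
            row = by_id.loc[rec.ligand_id]
            rec.class_label = str(row.get("label", rec.class_label))
            if "pharmacology" in by_id.columns and pd.notna(row.get("pharmacology")):
                rec.pharmacology = str(row["pharmacology"])


def load_library(
    sdf_source: str | Path | io.IOBase,
    labels: str | Path | pd.DataFrame | None = None,
) -> LigandLibrary:
    """Read an SDF ligand library into :class:`LigandLibrary`.

    ``sdf_source`` may be a path, raw SDF text, or a file-like object.
    Class labels come either from SDF tags (``class`` / ``pharmacology``)
    or from a sidecar CSV/DataFrame with columns
    ``ligand_id,label,pharmacology``.  Unparseable records are skipped
    and counted in ``n_skipped``.
    """
    if isinstance(sdf_source, io.IOBase):
        text = sdf_source.read()
        if isinstance(text, bytes):
            text = text.decode()
    else:
        path = Path(str(sdf_source))
        if "\n" in str(sdf_source) or "$$$$" in str(sdf_source):
            text = str(sdf_source)
        elif path.exists():
            text = path.read_text()
        else:
            raise LibraryError(f"cannot read SDF source {sdf_source!r}")
    if not text.strip():
        raise LibraryError("empty SDF source")

    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=True, removeHs=True)
    records: list[LigandRecord] = []
    n_skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        rec = _make_record(mol, name)
        if mol.HasProp("class"):
            rec.class_label = mol.GetProp("class")
        if mol.HasProp("pharmacology"):
            rec.pharmacology = mol.GetProp("pharmacology")
        records.append(rec)
    if n_skipped:
        logger.warning("skipped %d unparseable SDF record(s)", n_skipped)
    if not records:
        raise LibraryError("no valid records in SDF source")

    if labels is not None:
        if not isinstance(labels, pd.DataFrame):
            labels = pd.read_csv(labels)
        _apply_labels(records, labels)
    return LigandLibrary(records=records, n_skipped=n_skipped)


def racemize_library(library: LigandLibrary) -> LigandLibrary:
    """Flatten stereochemistry and set racemic bookkeeping.

    Every record is reduced to its 2D constitution; records with ≥1
    stereocenter are flagged racemic and their enantiomer multiplicity is
    2^n (label-only enumeration, capped at 2^10 with a warning —
    conformer generation for individual enantiomers is out of scope).
    """
    out: list[LigandRecord] = []
    for rec in library.records:
        flat = Chem.Mol(rec.mol)
        Chem.RemoveStereochemistry(flat)
        n_stereo = _count_stereocenters(flat)
        mult = 2**n_stereo
        if mult > MAX_ENANTIOMER_MULTIPLICITY:
            warnings.warn(
                f"{rec.ligand_id}: {n_stereo} stereocenters, capping multiplicity "
                f"at {MAX_ENANTIOMER_MULTIPLICITY}",
                stacklevel=2,
            )
            mult = MAX_ENANTIOMER_MULTIPLICITY
        out.append(
            replace(
                rec,
                mol=flat,
                constitution_key=_constitution_key(flat),
                n_stereocenters=n_stereo,
                racemic_flag=n_stereo >= 1,
                enantiomer_multiplicity=mult,
            )
        )
    return LigandLibrary(records=out, n_skipped=library.n_skipped)


def deduplicate(library: LigandLibrary) -> tuple[LigandLibrary, dict[str, str]]:
    """Merge records sharing a constitution so each compound counts once.

    Libraries that deposited both enantiomers of one compound collapse to
    a single record.  Returns the deduplicated library and a mapping
    old ligand_id → kept ligand_id for re-joining score tables.  Records
    with the same constitution but conflicting active/decoy labels raise
    :class:`LibraryError` naming the ids.
    """
    by_key: dict[str, list[LigandRecord]] = {}
    for rec in library.records:
        by_key.setdefault(rec.constitution_key, []).append(rec)

    out: list[LigandRecord] = []
    mapping: dict[str, str] = {}
    for key, group in by_key.items():
        group = sorted(group, key=lambda r: r.ligand_id)
        labels = {r.class_label for r in group}
        if len(labels) > 1:
            ids = [r.ligand_id for r in group]
            raise LibraryError(f"conflicting class labels {sorted(labels)} for duplicates {ids}")
        kept = group[0]
        pharm = {r.pharmacology for r in group} - {"unknown"}
        if len(pharm) == 1:
            kept = replace(kept, pharmacology=next(iter(pharm)))
        for r in group:
            mapping[r.ligand_id] = kept.ligand_id
        out.append(kept)
    out.sort(key=lambda r: r.ligand_id)
    if len(out) < len(library.records):
        logger.info(
            "deduplicated %d record(s) into %d unique constitutions",
            len(library.records),
            len(out),
        )
    return LigandLibrary(records=out, n_skipped=library.n_skipped), mapping


def _fingerprints(records: list[LigandRecord], radius: int = 2, n_bits: int = 2048):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return [gen.GetFingerprint(r.mol) for r in records]


def pairwise_dissimilarity(records: list[LigandRecord]) -> np.ndarray:
    """1 − Tanimoto similarity over Morgan fingerprints, as a square matrix."""
    fps = _fingerprints(records)
    n = len(fps)
    dist = np.zeros((n, n))
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        dist[i, i + 1 :] = 1.0 - np.asarray(sims)
    return dist + dist.T


def cluster_chemotypes(library: LigandLibrary, max_clusters: int = 4) -> ChemotypeClustering:
    """Cluster a known-ligand library into chemotype families.

    Complete-linkage hierarchical clustering on Tanimoto dissimilarity.
    The dendrogram is cut at the lowest height at which exactly
    ``max_clusters`` clusters of size ≥ 2 exist; if no height achieves
    that, the cut yielding ``max_clusters`` flat clusters is used.  The
    ``max_clusters`` largest clusters are named A, B, C, … in decreasing
    size (ties by lexicographically smallest member id); everything else
    is labeled "other".  Each named cluster's medoid (minimum summed
    dissimilarity) is its reported center.  The cut height is a
    per-library quantity, not comparable across libraries.

    Records also receive their label in ``record.chemotype``.
    """
    records = sorted(library.records, key=lambda r: r.ligand_id)
    ids = [r.ligand_id for r in records]
    n = len(records)
    if n == 0:
        raise LibraryError("cannot cluster an empty library")

    if n <= max_clusters:
        # fewer ligands than clusters: every ligand is its own cluster
        labels = {lid: chr(ord("A") + i) for i, lid in enumerate(ids)}
        centers = {v: k for k, v in labels.items()}
        _write_back(library, labels)
        return ChemotypeClustering(labels, centers, 0.0, max_clusters)

    dist = pairwise_dissimilarity(records)
    if np.allclose(dist, 0.0):
        labels = {lid: "A" for lid in ids}
        _write_back(library, labels)
        return ChemotypeClustering(labels, {"A": ids[0]}, 0.0, max_clusters, None)

    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")

    # Cut where exactly max_clusters clusters of size >= 2 exist.  The
    # count of such clusters rises and falls as the cut height grows; we
    # take the lowest height within the top-most band satisfying the
    # condition, so fully formed families are preferred over transient
    # partial pairings lower in the tree.
    chosen = None
    heights = sorted(set(np.concatenate([[0.0], link[:, 2]])))
    for h in reversed(heights):
        flat = hierarchy.fcluster(link, t=h, criterion="distance")
        sizes = np.bincount(flat)
        if (sizes >= 2).sum() == max_clusters:
            chosen, cut_height = flat, float(h)
            break
    if chosen is None:
        chosen = hierarchy.fcluster(link, t=max_clusters, criterion="maxclust")
        boundary = sorted(link[:, 2])[max(0, n - max_clusters - 1)]
        cut_height = float(boundary)

    groups: dict[int, list[int]] = {}
    for idx, c in enumerate(chosen):
        groups.setdefault(int(c), []).append(idx)
    ordered = sorted(
        groups.values(), key=lambda members: (-len(members), min(ids[i] for i in members))
    )

    labels = {}
    centers = {}
    for rank, members in enumerate(ordered):
        if rank < max_clusters and len(members) >= (2 if len(ordered) > max_clusters else 1):
            name = chr(ord("A") + rank)
        else:
            name = "other"
        for i in members:
            labels[ids[i]] = name
        if name != "other":
            sub = dist[np.ix_(members, members)]
            medoid_pos = min(
                range(len(members)), key=lambda k: (sub[k].sum(), ids[members[k]])
            )
            centers[name] = ids[members[medoid_pos]]

    _write_back(library, labels)
    return ChemotypeClustering(labels, centers, cut_height, max_clusters, link)


def _write_back(library: LigandLibrary, labels: Mapping[str, str]) -> None:
    for rec in library.records:
        rec.chemotype = labels.get(rec.ligand_id, "other")


def plot_dendrogram(clustering: ChemotypeClustering, ids: Iterable[str], path: str | Path) -> None:
    """Save the clustering dendrogram with the cut height marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if clustering.linkage_matrix is None:
        raise LibraryError("no linkage tree available (degenerate clustering)")
    fig, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(clustering.linkage_matrix, labels=list(ids), ax=ax)
    ax.axhline(clustering.linkage_height, ls=":", color="grey")
    ax.set_ylabel("complete-linkage dissimilarity (1 - Tanimoto)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
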