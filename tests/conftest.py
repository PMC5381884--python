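import numpy as np
import pandas as pd
import pytest

from pocketscreen import synthetic_data as sd


def make_score_table(
    active_scores, decoy_scores, repeat=1, pocket_id="p1", chemotype="A"
) -> pd.DataFrame:
    """Long-format score table from explicit per-class score lists."""
    rows = []
    for i, s in enumerate(active_scores):
        rows.append((f"act{i}", pocket_id, repeat, float(s), "active", "agonist", chemotype))
    for i, s in enumerate(decoy_scores):
        rows.append((f"dec{i}", pocket_id, repeat, float(s), "decoy", "unknown", "other"))
    return pd.DataFrame(
        rows,
        columns=["ligand_id", "pocket_id", "repeat", "score", "class_label",
                 "pharmacology", "chemotype"],
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def toy_spec() -> sd.ToyComplexSpec:
    """Miniature pocket realizing one interaction of each major class."""
    arom_dir = np.array([-0.695, -1.204, 3.5])
    arom_dist = float(np.linalg.norm(arom_dir))
    return sd.ToyComplexSpec(
        complex_id="toy1",
        placements=[
            sd.ResiduePlacement("ASP", 10, "OD1", "N1", 3.0, (1.0, 0.5, 0.0), "ionic"),
            sd.ResiduePlacement("LEU", 20, "CD1", "C5", 4.0, (-0.4, -1.0, 0.3), "hydrophobic"),
            sd.ResiduePlacement("SER", 30, "OG", "O1", 3.0, (-1.0, 0.0, 0.4), "hbond"),
            sd.ResiduePlacement("PHE", 40, "CG", "C2", arom_dist,
                                tuple(arom_dir / arom_dist), "aromatic"),
        ],
    )


@pytest.fixture
def toy_complex(toy_spec):
    return sd.build_toy_complex(toy_spec)
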