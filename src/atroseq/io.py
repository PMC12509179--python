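"""File formats and run configuration.

NIfTI-1 for maps and masks (float32 on disk, float64 internally for
statistics), TSV for tabular outputs, JSON for configuration, ground truth
and provenance sidecars.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_gm_map",
    "write_stat_map",
    "read_mask",
    "read_cohort",
    "write_cluster_table",
    "RunConfig",
    "config_hash",
    "write_provenance",
]


def read_gm_map(path):
    """Read one grey-matter map; returns ``(lattice float64, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def write_stat_map(data, affine, path, dtype=np.float32):
    """Write a lattice to NIfTI-1 (float32 by default)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(np.asarray(data, dtype=dtype), affine).to_filename(str(path))
    return path


def read_mask(path) -> np.ndarray:
    data, _ = read_gm_map(path)
    return data > 0.5


def read_cohort(cohort_dir):
    """Read ``participants.tsv`` + ``maps/<id>.nii[.gz]`` written by the generator.

    Returns ``(records, maps, affine)``; raises if any subject's map is
    missing or its shape disagrees with the rest (offending ids listed).
    """
    cohort_dir = Path(cohort_dir)
    records = pd.read_csv(cohort_dir / "participants.tsv", sep="\t")
    maps = []
    affine = None
    shape = None
    bad = []
    for sid in records["id"]:
        path = cohort_dir / "maps" / f"{sid}.nii"
        if not path.exists():
            path = cohort_dir / "maps" / f"{sid}.nii.gz"
        data, aff = read_gm_map(path)
        if shape is None:
            shape, affine = data.shape, aff
        elif data.shape != shape:
            bad.append(str(sid))
        maps.append(data)
    if bad:
        raise ValueError(f"map shape mismatch across subjects: {bad}")
    return records, np.stack(maps), affine


def write_cluster_table(clusters, path):
    """Cluster table TSV: cluster size, peak lattice + mm coordinates, statistic."""
    rows = []
    for rank, c in enumerate(clusters, start=1):
        mm = c.peak_mm or (np.nan, np.nan, np.nan)
        rows.append({
            "rank": rank,
            "cluster_size": c.size,
            "peak_i": c.peak_index[0], "peak_j": c.peak_index[1],
            "peak_k": c.peak_index[2],
            "peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2],
            "z_value": c.peak_stat,
        })
    df = pd.DataFrame(rows, columns=["rank", "cluster_size", "peak_i", "peak_j",
                                     "peak_k", "peak_x_mm", "peak_y_mm",
                                     "peak_z_mm", "z_value"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return df


@dataclass
class RunConfig:
    """Every numeric setting of the end-to-end pipeline, surfaced explicitly."""

    cohort_dir: str
    atlas_mask: str
    out_dir: str
    # voxel-based morphometry stage
    vbm_q: float = 0.005
    vbm_extent: int = 300
    # seed definition stage
    seed_alpha: float = 1e-5
    seed_extent: int = 500
    # causal structural covariance stage
    cascn_q: float = 0.001
    cascn_extent: int = 100
    # event-based model stage
    ebm_chains: int = 10
    greedy_iters: int = 10000
    mcmc_iters: int = 500000
    repeats: int = 10
    folds: int = 5
    adjust_biomarkers: bool = False
    # shared
    connectivity: int = 26
    mask_threshold: float = 0.1
    rng_seed: int = 0

    def validate(self):
        for name in ("vbm_q", "seed_alpha", "cascn_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("vbm_extent", "seed_extent", "cascn_extent", "ebm_chains",
                     "greedy_iters", "mcmc_iters", "repeats", "folds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not Path(self.cohort_dir).exists():
            raise FileNotFoundError(f"cohort directory not found: {self.cohort_dir}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the canonicalised configuration."""
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(path, cfg: RunConfig, extra: dict | None = None):
    """JSON sidecar: config, its hash, seed, package/library versions."""
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    payload = {
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "rng_seed": cfg.rng_seed,
        "versions": {
            "atroseq": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nib.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
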