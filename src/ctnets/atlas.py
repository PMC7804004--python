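"""Region atlas: names, hemispheres, homolog pairing and module labels.

The atlas mirrors the bookkeeping of a Destrieux-style cortical parcellation
(148 regions, 74 per hemisphere) as exported by FreeSurfer region statistics:
every left-hemisphere region has a contralateral homolog, and each region
carries a lobe label.  For synthetic cohorts the atlas additionally records
the ground-truth community (module) each region was generated from, which
downstream tests use to score community recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegionAtlas", "make_atlas", "read_atlas", "write_atlas"]

_LOBES = ("frontal", "temporal", "parietal", "occipital", "limbic", "insula")


@dataclass(frozen=True)
class RegionAtlas:
    """Immutable table of cortical regions.

    Attributes
    ----------
    names : array of str
        Region labels, index-aligned with thickness-matrix columns.
    hemisphere : array of str
        ``"left"`` or ``"right"`` per region.
    homolog_id : array of int
        Index of the contralateral homolog of each region.
    lobe : array of str
        Lobe label per region.
    true_module : array of int
        Ground-truth community id (synthetic cohorts only; -1 if unknown).
    """

    names: np.ndarray
    hemisphere: np.ndarray
    homolog_id: np.ndarray
    lobe: np.ndarray
    true_module: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.true_module is None:
            object.__setattr__(self, "true_module", np.full(n, -1, dtype=int))
        for attr in ("hemisphere", "homolog_id", "lobe", "true_module"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"atlas field {attr!r} length mismatch")
        h = np.asarray(self.homolog_id)
        if not np.array_equal(h[h], np.arange(n)):
            raise ValueError("homolog pairing must be symmetric and involutive")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    @property
    def homolog_pairs(self) -> np.ndarray:
        """(N/2, 2) array of homolog index pairs, left index first."""
        i = np.arange(self.n_regions)
        mask = i < self.homolog_id
        return np.column_stack([i[mask], self.homolog_id[mask]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n_regions),
                "name": self.names,
                "hemisphere": self.hemisphere,
                "homolog_id": self.homolog_id,
                "lobe": self.lobe,
                "true_module": self.true_module,
            }
        )


def make_atlas(n_regions: int, module_sizes: list[int]) -> RegionAtlas:
    """Build a synthetic two-hemisphere atlas with ground-truth modules.

    Regions ``0..n/2-1`` form the left hemisphere and region ``i`` is paired
    with its contralateral homolog ``i + n/2``.  Modules are contiguous
    blocks of region ids with the requested sizes (so a module may span the
    hemisphere boundary, as empirical covariance modules do).  Lobe labels
    cycle deterministically over the six cortical lobes within each
    hemisphere.

    Raises
    ------
    ValueError
        If ``n_regions`` is odd (homolog pairing requires an even count) or
        ``module_sizes`` does not sum to ``n_regions``.
    """
    if n_regions % 2 != 0:
        raise ValueError("homolog pairing requires even region count")
    if sum(module_sizes) != n_regions:
        raise ValueError(
            f"module_sizes sum to {sum(module_sizes)}, expected {n_regions}"
        )
    if any(s <= 0 for s in module_sizes):
        raise ValueError("module sizes must be positive")
    half = n_regions // 2
    hemisphere = np.array(["left"] * half + ["right"] * half)
    prefix = np.where(hemisphere == "left", "lh", "rh")
    local = np.concatenate([np.arange(half), np.arange(half)])
    names = np.array(
        [f"{p}.ctx_region_{j:03d}" for p, j in zip(prefix, local)]
    )
    homolog = np.concatenate([np.arange(half) + half, np.arange(half)])
    lobe = np.array([_LOBES[j % len(_LOBES)] for j in local])
    true_module = np.repeat(np.arange(len(module_sizes)), module_sizes)
    return RegionAtlas(names, hemisphere, homolog, lobe, true_module)


def write_atlas(atlas: RegionAtlas, path) -> None:
    atlas.to_frame().to_csv(path, index=False)


def read_atlas(path) -> RegionAtlas:
    df = pd.read_csv(path)
    df = df.sort_values("region_id").reset_index(drop=True)
    if not np.array_equal(df["region_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("region_ids must be unique and contiguous from 0")
    return RegionAtlas(
        names=df["name"].to_numpy(dtype=object),
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        homolog_id=df["homolog_id"].to_numpy(dtype=int),
        lobe=df["lobe"].to_numpy(dtype=object),
        true_module=df["true_module"].to_numpy(dtype=int),
    )
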