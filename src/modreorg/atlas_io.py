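"""Region atlas data model, file readers/writers and analysis configuration.

All on-disk interfaces speak 1-based region ids (the AAL convention).
Matrices are serialized as TSV with a region-id header, partitions as
two-column TSV, scalar and curve summaries as JSON. The bundled 116-region
atlas follows the conventional AAL ordering: odd id = left, even id = right
for ids 1-108, ids 109-116 are midline (vermis) regions without a homotopic
partner.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("modreorg")

# Left/right base names for ids 1-108 (odd = _L, even = _R), conventional
# AAL ordering, followed by the eight midline vermis regions (ids 109-116).
_AAL_BILATERAL = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf", "Cerebelum_Crus1",
    "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5", "Cerebelum_6",
    "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9", "Cerebelum_10",
]
_AAL_MIDLINE = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

# The eight homotopic pairs forming the largest bilateral module of the
# healthy group network (inferior frontal operculum, area triangularis,
# insula, putamen, globus pallidus, transverse temporal, superior temporal,
# superior temporal pole), as left/right AAL region ids.
INSULA_MODULE_REGIONS = [11, 12, 13, 14, 29, 30, 73, 74, 75, 76, 79, 80,
                         81, 82, 83, 84]


class AtlasError(ValueError):
    """Raised for invalid atlas files or inconsistent pairing."""


@dataclass(frozen=True)
class RegionAtlas:
    """Region identities, hemisphere labels and homotopic pairing.

    Parameters
    ----------
    region_ids : list of int
        1-based region ids, in file/matrix column order.
    names : list of str
        Region label per id.
    hemispheres : list of str
        One of ``left``, ``right``, ``midline`` per region.
    partners : dict
        Maps region id -> homotopic partner id; midline regions absent.
    named_subsets : dict
        Maps subset name -> list of region ids.
    """

    region_ids: tuple[int, ...]
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    partners: dict[int, int]
    named_subsets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.region_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if list(ids).count(i) > 1})
            raise AtlasError(f"duplicate region ids: {dupes}")
        idset = set(ids)
        hemi = dict(zip(ids, self.hemispheres))
        for h in self.hemispheres:
            if h not in ("left", "right", "midline"):
                raise AtlasError(f"unknown hemisphere label {h!r}")
        for i, j in self.partners.items():
            if i not in idset or j not in idset:
                raise AtlasError(f"pair ({i}, {j}) references unknown region")
            if self.partners.get(j) != i:
                raise AtlasError(
                    f"homotopic pairing is not involutive for pair ({i}, {j}): "
                    f"partner({j}) = {self.partners.get(j)}"
                )
            if i == j:
                raise AtlasError(f"region {i} paired with itself")
            if {hemi[i], hemi[j]} != {"left", "right"}:
                raise AtlasError(
                    f"pair ({i}, {j}) must contain one left and one right "
                    f"region, got ({hemi[i]}, {hemi[j]})"
                )
        for i, h in zip(ids, self.hemispheres):
            if h == "midline" and i in self.partners:
                raise AtlasError(f"midline region {i} has a homotopic partner")
        for name, subset in self.named_subsets.items():
            missing = sorted(set(subset) - idset)
            if missing:
                raise AtlasError(
                    f"subset {name!r} references unknown regions {missing}"
                )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: int) -> int:
        """0-based matrix column index of a 1-based region id."""
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise AtlasError(f"unknown region id {region_id}") from None

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """All (left_id, right_id) homotopic pairs, ordered by left id."""
        hemi = dict(zip(self.region_ids, self.hemispheres))
        pairs = [(i, j) for i, j in self.partners.items()
                 if hemi[i] == "left"]
        return sorted(pairs)

    def subset_pairs(self, subset: str | None = None) -> list[tuple[int, int]]:
        """Homotopic (left, right) pairs restricted to a named subset.

        ``subset=None`` returns every pair in the atlas. Raises if the
        subset name is unknown or the subset contains unpaired regions.
        """
        pairs = self.homotopic_pairs()
        if subset is None:
            return pairs
        if subset not in self.named_subsets:
            raise AtlasError(
                f"unknown subset {subset!r}; available: "
                f"{sorted(self.named_subsets)}"
            )
        members = set(self.named_subsets[subset])
        chosen = [(i, j) for i, j in pairs if i in members and j in members]
        unpaired = members - {r for p in chosen for r in p}
        if unpaired:
            raise AtlasError(
                f"subset {subset!r} members {sorted(unpaired)} are not part "
                "of a homotopic pair inside the subset"
            )
        return chosen

    def midline_ids(self) -> list[int]:
        return [i for i, h in zip(self.region_ids, self.hemispheres)
                if h == "midline"]


def default_atlas() -> RegionAtlas:
    """The bundled 116-region atlas (54 homotopic pairs, 8 midline regions)."""
    ids, names, hemis = [], [], []
    partners: dict[int, int] = {}
    for k, base in enumerate(_AAL_BILATERAL):
        left, right = 2 * k + 1, 2 * k + 2
        ids += [left, right]
        names += [f"{base}_L", f"{base}_R"]
        hemis += ["left", "right"]
        partners[left] = right
        partners[right] = left
    for k, name in enumerate(_AAL_MIDLINE):
        ids.append(109 + k)
        names.append(name)
        hemis.append("midline")
    return RegionAtlas(
        region_ids=tuple(ids),
        names=tuple(names),
        hemispheres=tuple(hemis),
        partners=partners,
        named_subsets={"insula_module_pairs": tuple(INSULA_MODULE_REGIONS)},
    )


def read_atlas(path: str | Path) -> RegionAtlas:
    """Read an atlas TSV with columns region_id, name, hemisphere,
    homotopic_partner (empty/0 = none). Optional extra columns named
    ``subset:<name>`` with 0/1 flags define named subsets."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "hemisphere": str})
    required = {"region_id", "name", "hemisphere", "homotopic_partner"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"atlas file missing columns: {sorted(missing)}")
    ids = [int(i) for i in df["region_id"]]
    partners: dict[int, int] = {}
    for rid, p in zip(ids, df["homotopic_partner"]):
        if pd.isna(p) or int(p) == 0:
            continue
        partners[rid] = int(p)
    subsets = {}
    for col in df.columns:
        if col.startswith("subset:"):
            members = tuple(int(i) for i, flag in zip(ids, df[col])
                            if not pd.isna(flag) and int(flag) == 1)
            subsets[col[len("subset:"):]] = members
    return RegionAtlas(
        region_ids=tuple(ids),
        names=tuple(str(n) for n in df["name"]),
        hemispheres=tuple(str(h) for h in df["hemisphere"]),
        partners=partners,
        named_subsets=subsets,
    )


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    rows = {
        "region_id": list(atlas.region_ids),
        "name": list(atlas.names),
        "hemisphere": list(atlas.hemispheres),
        "homotopic_partner": [atlas.partners.get(i, 0)
                              for i in atlas.region_ids],
    }
    for name, subset in sorted(atlas.named_subsets.items()):
        members = set(subset)
        rows[f"subset:{name}"] = [int(i in members) for i in atlas.region_ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SubjectTimeSeries:
    """One subject's T x N region-averaged signal matrix."""

    subject_id: str
    group: str
    data: np.ndarray
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D matrix")
        if self.data.shape[0] < 3:
            raise ValueError(
                f"subject {self.subject_id}: need at least 3 time points, "
                f"got {self.data.shape[0]}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: missing or "
                             "non-finite values in time series")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def read_timeseries(path: str | Path, atlas: RegionAtlas,
                    subject_id: str | None = None,
                    group: str = "") -> SubjectTimeSeries:
    """Read a T x N TSV/CSV with a header of region ids or names; columns
    are reordered to atlas order."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    colmap: dict[str, int] = {}
    for rid, name in zip(atlas.region_ids, atlas.names):
        colmap[str(rid)] = rid
        colmap[name] = rid
    by_id: dict[int, str] = {}
    for col in df.columns:
        if str(col) in colmap:
            by_id[colmap[str(col)]] = col
    missing = [rid for rid in atlas.region_ids if rid not in by_id]
    if missing:
        raise ValueError(
            f"{path.name}: missing region columns {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''} "
            f"({len(df.columns)} columns vs {atlas.n_regions} regions)"
        )
    ordered = df[[by_id[rid] for rid in atlas.region_ids]]
    try:
        data = ordered.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path.name}: non-numeric cell in matrix: {exc}")
    return SubjectTimeSeries(subject_id=subject_id or path.stem,
                             group=group, data=data)


def write_timeseries(ts: SubjectTimeSeries, atlas: RegionAtlas,
                     path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=[str(i) for i in atlas.region_ids]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


@dataclass
class AnalysisConfig:
    """Knobs shared across pipeline stages; every output records the seed."""

    seed: int = 0
    ne_grid: tuple[int, ...] = tuple(range(200, 2001, 200))
    n_null: int = 100
    alpha: float = 0.05
    positive_mask: str = "group"      # "group" | "subject"
    std_mode: str = "population"      # "population" | "sample"
    refine: bool = True
    index_b_mode: str = "distinct"    # "distinct" | "literal"
    pairs_subset: str = "insula_module_pairs"
    classify_features: tuple[str, ...] = ("index_A", "gmc_module_mean")
    classify_groups: tuple[str, str] = ("CN", "AD")

    def __post_init__(self) -> None:
        self.ne_grid = tuple(int(x) for x in self.ne_grid)
        if any(x < 1 for x in self.ne_grid):
            raise ValueError("ne_grid entries must be >= 1")

    def validate_grid(self, n_regions: int) -> None:
        cap = n_regions * (n_regions - 1) // 2
        bad = [x for x in self.ne_grid if x > cap]
        if bad:
            raise ValueError(f"ne_grid entries {bad} exceed the "
                             f"{cap} possible edges for N={n_regions}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ne_grid"] = list(self.ne_grid)
        d["classify_features"] = list(self.classify_features)
        d["classify_groups"] = list(self.classify_groups)
        return d


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key in ("ne_grid", "classify_features", "classify_groups"):
        parts = [p.strip() for p in raw.split(",") if p.strip()]
        if key == "ne_grid":
            if len(parts) == 1 and ":" in parts[0]:
                start, stop, step = (int(x) for x in parts[0].split(":"))
                return tuple(range(start, stop + 1, step))
            return tuple(int(p) for p in parts)
        return tuple(parts)
    if key == "refine":
        return raw.lower() in ("1", "true", "yes", "on")
    if key in ("seed", "n_null"):
        return int(raw)
    if key == "alpha":
        return float(raw)
    return raw


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    values: dict = {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _parse_value(key, raw)
    return AnalysisConfig(**values)


# ---------------------------------------------------------------------------
# Result writers


def write_matrix(matrix: np.ndarray, atlas: RegionAtlas,
                 path: str | Path) -> None:
    """Write an N x N matrix as TSV with a region-id header column and row."""
    ids = [str(i) for i in atlas.region_ids]
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="region_id", float_format="%.17g")


def read_matrix(path: str | Path, atlas: RegionAtlas) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col="region_id",
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    ids = [str(i) for i in atlas.region_ids]
    return df.loc[ids, ids].to_numpy(dtype=float)


def write_partition(labels: np.ndarray, atlas: RegionAtlas,
                    path: str | Path) -> None:
    pd.DataFrame({
        "region_id": list(atlas.region_ids),
        "module": [int(m) for m in labels],
    }).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path, atlas: RegionAtlas) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df["region_id"].astype(int), df["module"].astype(int)))
    return np.array([mapping[i] for i in atlas.region_ids], dtype=int)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_results(objects: dict[str, object], out_dir: str | Path,
                  config: AnalysisConfig | None = None,
                  atlas: RegionAtlas | None = None) -> dict:
    """Write a dict of pipeline products under ``out_dir`` and return the
    manifest (also written as ``manifest.json``).

    Matrices need an atlas and go to ``<name>.tsv``; dict/list values go to
    ``<name>.json``. File names are deterministic; the manifest records the
    config, seed and library versions (no timestamps, so reruns are
    byte-identical).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        files = {}
        for name, obj in sorted(objects.items()):
            if isinstance(obj, np.ndarray) and obj.ndim == 2:
                if atlas is None:
                    raise ValueError(f"{name}: matrix output needs an atlas")
                fname = f"{name}.tsv"
                write_matrix(obj, atlas, out / fname)
            else:
                fname = f"{name}.json"
                write_json(obj, out / fname)
            files[name] = fname
        manifest = {
            "files": files,
            "config": config.to_dict() if config else None,
            "seed": config.seed if config else None,
            "versions": {
                "modreorg": _version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": sys.version.split()[0],
            },
        }
        write_json(manifest, out / "manifest.json")
    except OSError as exc:
        raise OSError(f"cannot write results under {out}: {exc}") from exc
    return manifest


def _version() -> str:
    from modreorg import __version__
    return __version__
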