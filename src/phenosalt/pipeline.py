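"""Run configuration, trait-table IO, and the end-to-end pipeline.

One sample = one hyperspectral cube + one point cloud, joined on sample_id.
The pipeline extracts the 19 computing traits (3 structural + 16 spectral),
grades every sample with the entropy-weighted fuzzy evaluator, produces the
trait statistics table and the PCA baseline, and writes a report that echoes
the exact configuration used.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from phenosalt import fce, spectral, structural, suite
from phenosalt.fixtures import CPT_TRAIT_NAMES

__all__ = [
    "RunConfig",
    "read_trait_matrix",
    "write_trait_table",
    "upsert_trait_rows",
    "read_polarity",
    "write_ratings",
    "read_ratings",
    "run_pipeline",
    "DEFAULT_POLARITY",
]

#: Default indicator polarity for the 19 computing traits. The Carter stress
#: ratio rises under stress, so it is the one negative indicator by default;
#: everything else tracks vigour. Override with a polarity file.
DEFAULT_POLARITY: dict[str, str] = {
    name: ("negative" if name == "CTR" else "positive") for name in CPT_TRAIT_NAMES
}


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, serializable to YAML."""

    tvi_threshold: float = spectral.DEFAULT_TVI_THRESHOLD
    band_tolerance: float = spectral.DEFAULT_BAND_TOLERANCE
    grid_cell: float = structural.DEFAULT_GRID_CELL
    knn: int = 16
    std_multiplier: float = 2.0
    voxel_size: float = 0.25
    canopy_fraction: float = 0.5
    mls_radius: float = 1.0
    unit_scale: float = 1.0
    breakpoints: tuple[float, ...] = fce.DEFAULT_BREAKPOINTS
    grades: tuple[str, ...] = fce.DEFAULT_GRADES
    scores: tuple[float, ...] = fce.DEFAULT_SCORES
    reference_trait: str = "NDVI"
    seed: int = 0

    def filter_config(self) -> structural.FilterConfig:
        return structural.FilterConfig(
            knn=self.knn,
            std_multiplier=self.std_multiplier,
            voxel_size=self.voxel_size,
            canopy_fraction=self.canopy_fraction,
            mls_radius=self.mls_radius,
        )

    def membership_params(self) -> fce.MembershipParams:
        return fce.MembershipParams(breakpoints=tuple(self.breakpoints))

    def evaluation_set(self) -> fce.EvaluationSet:
        return fce.EvaluationSet(
            grades=tuple(self.grades), scores=tuple(float(s) for s in self.scores)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["breakpoints"] = list(self.breakpoints)
        d["grades"] = list(self.grades)
        d["scores"] = list(self.scores)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("breakpoints", "grades", "scores"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Trait tables and companion files


def read_polarity(path: str) -> dict[str, str]:
    """Read a ``trait_name,polarity`` CSV (no header required)."""
    polarity: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.lower().startswith("trait_name"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2 or parts[1] not in ("positive", "negative"):
                raise ValueError(
                    f"{path}:{lineno}: expected 'trait_name,positive|negative'"
                )
            polarity[parts[0]] = parts[1]
    if not polarity:
        raise ValueError(f"{path}: empty polarity file")
    return polarity


def write_polarity(polarity: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("trait_name,polarity\n")
        for name, pol in polarity.items():
            fh.write(f"{name},{pol}\n")


def read_trait_matrix(
    traits_csv: str, polarity: dict[str, str] | str | None = None
) -> fce.TraitMatrix:
    """Load a trait matrix CSV (sample-id column + one column per trait).

    ``polarity`` may be a mapping, a polarity CSV path, or None (all traits
    positive, except the built-in defaults for known trait names).
    """
    df = pd.read_csv(traits_csv)
    if df.shape[1] < 2:
        raise ValueError(f"{traits_csv}: need a sample-id column plus traits")
    id_col = df.columns[0]
    trait_names = [str(c) for c in df.columns[1:]]
    if isinstance(polarity, str):
        polarity = read_polarity(polarity)
    if polarity is None:
        polarity = {}
    pol = [
        polarity.get(name, DEFAULT_POLARITY.get(name, "positive"))
        for name in trait_names
    ]
    return fce.TraitMatrix(
        sample_ids=[str(s) for s in df[id_col]],
        trait_names=trait_names,
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        polarity=pol,
    )


def write_trait_table(matrix: fce.TraitMatrix, path: str) -> None:
    df = pd.DataFrame(
        matrix.values, columns=matrix.trait_names, index=matrix.sample_ids
    )
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def upsert_trait_rows(path: str, sample_id: str, values: dict[str, float]) -> None:
    """Merge one sample's trait values into a (possibly existing) CSV table."""
    if os.path.exists(path):
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
    else:
        df = pd.DataFrame()
        df.index.name = "sample_id"
    for name, value in values.items():
        df.loc[sample_id, name] = value
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def write_ratings(
    evaluations: list[fce.FuzzyEvaluation], path: str
) -> None:
    rows = []
    for e in evaluations:
        row = {"sample_id": e.sample_id}
        for k, bk in enumerate(e.b, start=1):
            row[f"b{k}"] = bk
        row["grade"] = e.grade
        row["score"] = e.score
        row["expected_score"] = e.expected_score
        row["tie"] = e.tie
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_ratings(path: str) -> dict[str, str]:
    """Read ``sample_id -> grade`` from a ratings CSV."""
    df = pd.read_csv(path)
    if "grade" not in df.columns:
        raise ValueError(f"{path}: ratings CSV must have a 'grade' column")
    id_col = "sample_id" if "sample_id" in df.columns else df.columns[0]
    return {str(s): str(g) for s, g in zip(df[id_col], df["grade"])}


def write_stats_table(rows: list[suite.TraitStats], path: str) -> None:
    df = pd.DataFrame(
        [{"trait_name": r.trait_name, "cv": r.cv, "h": r.h, "var": r.var} for r in rows]
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_pca_result(result: suite.PcaResult, path: str) -> None:
    df = pd.DataFrame(
        {
            "sample_id": result.sample_ids,
            "pc1_score": result.pc1_scores,
            "rank": result.ranks,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _extract_sample_traits(
    entry: dict, config: RunConfig
) -> tuple[str, dict[str, float]]:
    sid = str(entry.get("id", ""))
    if not sid:
        raise ValueError("manifest sample entry is missing an 'id'")
    values: dict[str, float] = {}
    if "cube" in entry:
        path = entry["cube"]
        if not os.path.exists(path) and not os.path.exists(path + ".hdr"):
            raise FileNotFoundError(f"sample {sid}: cube file not found: {path}")
        cube = spectral.load_cube(path)
        tvi = spectral.compute_index(cube, "TVI")
        # undefined pixels cannot be vegetation
        tvi = np.where(np.isfinite(tvi), tvi, -1e30)
        mask = spectral.segment_vegetation(tvi, config.tvi_threshold)
        vec = spectral.extract_spectral_traits(cube, mask, sid)
        values.update(vec.values)
    if "points" in entry:
        path = entry["points"]
        if not os.path.exists(path):
            raise FileNotFoundError(f"sample {sid}: point cloud not found: {path}")
        cloud = structural.load_points(path, sample_id=sid, unit_scale=config.unit_scale)
        traits = structural.extract_structural_traits(
            cloud, config.filter_config(), cell=config.grid_cell
        )
        values["Height"] = traits.height
        values["Leaf-area"] = traits.canopy_leaf_area
        values["Volume"] = traits.volume
    if not values:
        raise ValueError(f"sample {sid}: manifest entry has neither cube nor points")
    return sid, values


def run_pipeline(config: RunConfig, manifest: dict, out_dir: str) -> dict:
    """Execute the full pipeline and write the report bundle into ``out_dir``.

    The manifest maps inputs: a ``samples`` list of ``{id, cube, points}``
    entries and/or a ``traits`` CSV path, plus optional ``polarity`` and
    ``compare_with`` (a second ratings CSV for the consistency rate). All
    outputs are written only after every stage succeeds; any stage error
    aborts the run with the failing sample named and leaves nothing behind.
    """
    polarity = None
    if manifest.get("polarity"):
        polarity = read_polarity(manifest["polarity"])

    rows: dict[str, dict[str, float]] = {}
    for entry in manifest.get("samples", []):
        try:
            sid, values = _extract_sample_traits(entry, config)
        except Exception as e:
            sid = entry.get("id", "<unknown>")
            raise RuntimeError(f"trait extraction failed for sample {sid}: {e}") from e
        rows[sid] = values

    if manifest.get("traits"):
        base = read_trait_matrix(manifest["traits"], polarity)
        for i, sid in enumerate(base.sample_ids):
            merged = dict(zip(base.trait_names, base.values[i]))
            merged.update(rows.get(sid, {}))
            rows[sid] = merged

    if not rows:
        raise ValueError("manifest provided no samples and no trait table")

    trait_names = sorted({t for v in rows.values() for t in v}, key=str)
    # prefer the canonical ordering when all names are canonical
    if set(trait_names) <= set(CPT_TRAIT_NAMES):
        trait_names = [t for t in CPT_TRAIT_NAMES if t in set(trait_names)]
    sample_ids = list(rows)
    values = np.empty((len(sample_ids), len(trait_names)))
    for i, sid in enumerate(sample_ids):
        missing = [t for t in trait_names if t not in rows[sid]]
        if missing:
            raise ValueError(f"sample {sid} is missing traits {missing}")
        values[i] = [rows[sid][t] for t in trait_names]
    pol_map = dict(DEFAULT_POLARITY)
    if polarity:
        pol_map.update(polarity)
    matrix = fce.TraitMatrix(
        sample_ids=sample_ids,
        trait_names=trait_names,
        values=values,
        polarity=[pol_map.get(t, "positive") for t in trait_names],
    )

    evaluations, weights = fce.evaluate(
        matrix, config.membership_params(), config.evaluation_set()
    )
    reference = (
        config.reference_trait
        if config.reference_trait in trait_names
        else trait_names[0]
    )
    # the PCA baseline and the stats table need at least 3 samples
    pca = agreement = stats_rows = None
    if len(sample_ids) >= 3:
        stats_rows = suite.trait_stats_table(matrix)
        pca = suite.pca_composite(matrix, reference)
        agreement = suite.rank_agreement(evaluations, pca)

    consistency = None
    if manifest.get("compare_with"):
        other = read_ratings(manifest["compare_with"])
        mine = {e.sample_id: e.grade for e in evaluations}
        consistency = suite.consistency_rate(mine, other)

    report = {
        "config": config.to_dict(),
        "manifest": manifest,
        "n_samples": len(sample_ids),
        "trait_names": trait_names,
        "reference_trait": reference,
        "weights": {n: float(w) for n, w in zip(weights.trait_names, weights.weights)},
        "divergences": {
            n: float(d) for n, d in zip(weights.trait_names, weights.divergences)
        },
        "entropies": {
            n: float(e) for n, e in zip(weights.trait_names, weights.entropies)
        },
        "pca_explained_fraction": pca.explained_fraction if pca else None,
        "fce_pca_rank_agreement": agreement,
        "consistency_rate": consistency,
    }

    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    try:
        def _path(name: str) -> str:
            p = os.path.join(out_dir, name)
            written.append(p)
            return p

        write_trait_table(matrix, _path("traits.csv"))
        write_ratings(evaluations, _path("ratings.csv"))
        if stats_rows is not None:
            write_stats_table(stats_rows, _path("stats.csv"))
        if pca is not None:
            write_pca_result(pca, _path("pca.csv"))
        with open(_path("report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise
    return report
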