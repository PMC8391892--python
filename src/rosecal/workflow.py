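"""Configuration-driven pipelines: simulate -> preprocess -> calibrate/cluster.

``run_calibration`` reproduces the full experimental grid of the
adulteration study on simulated data: for each of the seven
oil-adulterant series (its eight concentration levels), each regression
method (PLSR, PCR) and each preprocessing variant (raw, first and second
derivative), the calibration set is built on the adulterant-specific
quantification window and leave-one-out cross-validated at the
configured factor count.  ``run_clustering`` applies the classification
pipeline (second derivative + vector normalization over the two survey
windows) to all samples and exports the Ward dendrogram and PCA scores.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import Dendrogram, PcaResult, export_newick, hca_ward, pca_decompose
from .exceptions import ConfigError
from .preprocess import VARIANTS, PreprocessSpec, apply_pipeline
from .regression import CalibrationSet, loo_cross_validate
from .spectra import WavenumberWindow
from .synth import (
    ComponentLibrary,
    DesignRow,
    SyntheticDataset,
    component_of_brand,
    default_grid,
    default_library,
    generate_design,
    generate_dataset,
)

__all__ = [
    "RunConfig",
    "run_calibration",
    "run_clustering",
    "write_calibration_csv",
]

_DEFAULT_ADULTERANT_WINDOWS = {
    "PEO": (1700.0, 1600.0),
    "GEO": (1218.0, 1130.0),
    "PEOH": (710.0, 690.0),
}
_DEFAULT_HCA_WINDOWS = ((3541.0, 3153.0), (1771.0, 663.0))


@dataclass
class RunConfig:
    """Everything a reproducible run needs; loadable from YAML/JSON.

    ``adulterant_windows`` maps adulterant components to their
    quantification windows (high, low in cm^-1); ``hca_windows`` are the
    survey ranges used for classification.
    """

    grid_high: float = 4000.0
    grid_low: float = 600.0
    grid_step: float = 2.0
    library: str = "default"
    design: str = "paper"
    noise_sd: float = 0.003
    baseline_slope: float = 0.0
    seed: int | None = 0
    preprocessings: tuple[str, ...] = ("raw", "first_derivative", "second_derivative")
    adulterant_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ADULTERANT_WINDOWS)
    )
    hca_windows: tuple[tuple[float, float], ...] = _DEFAULT_HCA_WINDOWS
    methods: tuple[str, ...] = ("PLSR", "PCR")
    k: int = 3
    sg_window: int = 9
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.grid_high <= self.grid_low:
            raise ConfigError("grid: requires grid_high > grid_low and grid_step > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ConfigError("seed: required when noise_sd > 0")
        for name in self.preprocessings:
            if name not in VARIANTS:
                raise ConfigError(
                    f"preprocessings: unknown variant {name!r} "
                    f"(choose from {sorted(VARIANTS)})"
                )
        for m in self.methods:
            if m.upper() not in ("PLSR", "PCR"):
                raise ConfigError(f"methods: unknown method {m!r}")
        if self.k < 1:
            raise ConfigError("k: must be >= 1")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        doc = dict(doc)
        if "adulterant_windows" in doc:
            doc["adulterant_windows"] = {
                k: tuple(map(float, v)) for k, v in doc["adulterant_windows"].items()
            }
        if "hca_windows" in doc:
            doc["hca_windows"] = tuple(
                tuple(map(float, w)) for w in doc["hca_windows"]
            )
        for key in ("preprocessings", "methods"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("configuration document must be a mapping")
        return cls.from_dict(doc)

    def make_grid(self) -> np.ndarray:
        return default_grid(self.grid_high, self.grid_low, self.grid_step)

    def make_library(self) -> ComponentLibrary:
        if self.library == "default":
            return default_library()
        return ComponentLibrary.from_yaml(self.library)

    def make_design(self) -> list[DesignRow]:
        if self.design == "paper":
            return generate_design()
        ref = pd.read_csv(self.design)
        required = {"sample_id", "base_brand", "adulterant", "level"}
        if not required.issubset(ref.columns):
            raise ConfigError(f"design: CSV must have columns {sorted(required)}")
        return [
            DesignRow(str(r.sample_id), str(r.base_brand), str(r.adulterant), float(r.level))
            for r in ref.itertuples()
        ]

    def make_dataset(self) -> SyntheticDataset:
        design = self.make_design()
        for row in design:
            if row.adulterant == "none":
                continue
            comp = component_of_brand(row.adulterant)
            if comp not in self.adulterant_windows:
                raise ConfigError(
                    f"adulterant_windows: no window for adulterant {comp!r}"
                )
        return generate_dataset(
            self.make_library(),
            design,
            noise_sd=self.noise_sd,
            baseline_slope=self.baseline_slope,
            seed=self.seed or 0,
            grid=self.make_grid(),
        )


def run_calibration(config: RunConfig) -> pd.DataFrame:
    """One metrics row per (series, method, preprocessing) combination."""
    dataset = config.make_dataset()
    by_id = {s.sample_id: s for s in dataset.spectra}

    series_order: list[str] = []
    series_rows: dict[str, list[DesignRow]] = {}
    for row in dataset.reference:
        if row.series not in series_rows:
            series_rows[row.series] = []
            series_order.append(row.series)
        series_rows[row.series].append(row)

    records = []
    for series in series_order:
        rows = sorted(series_rows[series], key=lambda r: r.level)
        adulterant_brand, base_brand = series.split("_", 1)
        comp = component_of_brand(adulterant_brand)
        high, low = config.adulterant_windows[comp]
        window = WavenumberWindow(high=high, low=low)
        spectra = [by_id[r.sample_id] for r in rows]
        y = np.array([r.level for r in rows])
        for prep_name in config.preprocessings:
            spec = PreprocessSpec(
                derivative_order=VARIANTS[prep_name],
                sg_window=config.sg_window,
                sg_polyorder=config.sg_polyorder,
                normalize=False,
            )
            X = apply_pipeline(spectra, spec, [window]).to_numpy()
            calset = CalibrationSet(X, y, [r.sample_id for r in rows])
            for method in config.methods:
                res = loo_cross_validate(calset, method, config.k)
                records.append(
                    {
                        "sample_code": f"{adulterant_brand} {base_brand}",
                        "method": method.upper(),
                        "preprocessing": prep_name,
                        "factors": res.k,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "r2": res.r2,
                        "press": res.press,
                        "secv": res.secv,
                        "bias": res.bias,
                    }
                )
    return pd.DataFrame.from_records(records)


def write_calibration_csv(results: pd.DataFrame, path) -> None:
    """Serialize the metrics table with stable full-precision formatting."""
    buf = io.StringIO()
    results.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def run_clustering(
    config: RunConfig, outdir=None
) -> tuple[Dendrogram, PcaResult]:
    """Classification pipeline over all samples; optionally write artifacts.

    Writes ``dendrogram.nwk``, ``merges.csv`` and ``pca_scores.csv`` when
    ``outdir`` is given.
    """
    dataset = config.make_dataset()
    windows = [WavenumberWindow(high=h, low=l) for h, l in config.hca_windows]
    spec = PreprocessSpec(
        derivative_order=2,
        sg_window=config.sg_window,
        sg_polyorder=config.sg_polyorder,
        normalize=True,
    )
    X = apply_pipeline(dataset.spectra, spec, windows)
    ids = list(X.index)
    dendrogram = hca_ward(X.to_numpy(), ids)
    pca = pca_decompose(X.to_numpy(), n_components=3)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "dendrogram.nwk").write_text(export_newick(dendrogram) + "\n")
        pd.DataFrame(
            dendrogram.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        ).to_csv(outdir / "merges.csv", index=False)
        scores = pd.DataFrame(
            pca.scores, columns=["PC1", "PC2", "PC3"]
        )
        scores.insert(0, "sample_id", ids)
        scores.to_csv(outdir / "pca_scores.csv", index=False)
    return dendrogram, pca
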