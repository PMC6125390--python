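"""End-to-end orchestration: preprocessing -> feature extraction -> prognosis.

One image yields 34 features: 2 staining-intensity features plus 32 fractal
features (3 monofractal + 13 multifractal, each for the binary and the
grayscale modality).  A batch run never aborts on a single bad image: the
failure is logged as a structured JSON event and the run continues.

Every run is reproducible bit-for-bit from its :class:`RunConfig` and seed,
including all bootstrap draws.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import image_prep, intensity, monofractal, multifractal, prognostics

SCHEMA_VERSION = "1"

MULTIFRACTAL_NAMES = [
    "d_q0",
    "alpha_q0",
    "f_alpha_q0",
    "d_q_max",
    "f_alpha_min",
    "f_alpha_max",
    "alpha_at_f_min",
    "alpha_at_f_max",
    "slope_dq",
    "slope_alpha",
    "slope_falpha",
    "slope_dq_restricted",
    "f_alpha_sum_qpos",
]

#: the 34-column per-image feature schema: 2 intensity + 32 fractal
FEATURE_COLUMNS = (
    ["mean_intensity", "total_area_px"]
    + ["bin_fd", "bin_fd_outline", "bin_lac", "gray_fd", "gray_fd_outline", "gray_lac"]
    + [f"bin_mf_{n}" for n in MULTIFRACTAL_NAMES]
    + [f"gray_mf_{n}" for n in MULTIFRACTAL_NAMES]
)

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")


class RunError(RuntimeError):
    pass


@dataclass
class RunConfig:
    input_dir: str = ""
    output_dir: str = "out"
    pixel_size: float = image_prep.DEFAULT_PIXEL_SIZE_UM
    n_boot: int = 1000
    seed: int = 0
    min_group_frac: float = 0.10

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def extract_features(gray: image_prep.GrayImage) -> dict[str, float]:
    """All 34 features (plus fit diagnostics) for one grayscale image."""
    bin_img = image_prep.binarize(gray)
    outline = image_prep.extract_outline(bin_img)
    feats = intensity.intensity_features(gray, bin_img)
    mono_bin, mono_gray = monofractal.monofractal_features(gray, bin_img, outline)
    mf_bin, mf_gray = multifractal.multifractal_features(gray, bin_img)

    row: dict[str, float] = {
        "mean_intensity": feats.mean_intensity,
        "total_area_px": float(feats.total_area_px),
        "bin_fd": mono_bin.fd,
        "bin_fd_outline": mono_bin.fd_outline,
        "bin_lac": mono_bin.lacunarity,
        "gray_fd": mono_gray.fd,
        "gray_fd_outline": mono_gray.fd_outline,
        "gray_lac": mono_gray.lacunarity,
    }
    for prefix, mf in (("bin_mf_", mf_bin), ("gray_mf_", mf_gray)):
        for name, value in mf.as_dict().items():
            row[prefix + name] = value
    # diagnostics, not part of the feature schema
    row["total_area_um2"] = feats.total_area_um2
    row["bin_fit_r2"] = mono_bin.r_squared
    row["gray_fit_r2"] = mono_gray.r_squared
    return row


def run_extract(
    config: RunConfig, log: list[dict] | None = None
) -> pd.DataFrame:
    """Extract the feature table for every image in ``config.input_dir``.

    Per-image failures are appended to ``log`` as JSON-serializable records
    and the image is skipped; an empty input directory is a run error.
    """
    log = log if log is not None else []
    in_dir = Path(config.input_dir)
    paths = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    ) if in_dir.is_dir() else []
    if not paths:
        raise RunError(f"no input images found under {config.input_dir!r}")

    rows = []
    for path in paths:
        try:
            gray = image_prep.load_gray(path, config.pixel_size)
            row = {"image": path.name, **extract_features(gray)}
            rows.append(row)
            log.append({"event": "extracted", "image": path.name,
                        "bin_fit_r2": row["bin_fit_r2"]})
        except Exception as exc:  # noqa: BLE001 - batch must survive bad crops
            log.append({"event": "skipped", "image": path.name, "reason": str(exc)})
    if not rows:
        raise RunError("every input image failed feature extraction")
    df = pd.DataFrame(rows)
    ordered = ["image"] + FEATURE_COLUMNS + ["total_area_um2", "bin_fit_r2", "gray_fit_r2"]
    return df[ordered]


def write_features(df: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# histofract feature schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_features(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_prognosis(
    config: RunConfig,
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    feature_columns: list[str] | None = None,
) -> dict[str, object]:
    """Full prognostic report for a joined feature/cohort table.

    ``features`` must carry ``patient_id`` plus feature columns; ``cohort``
    carries ``patient_id``, ``time_months`` and ``event``.  The tables must
    join 1:1.  Returns a dict with the per-feature report, the multivariate
    model, the Spearman matrix and per-feature Kaplan-Meier curves.
    """
    for col in ("patient_id",):
        if col not in features or col not in cohort:
            raise RunError("both tables need a patient_id column")
    orphans = set(features.patient_id).symmetric_difference(cohort.patient_id)
    if orphans:
        raise RunError(f"feature/cohort tables do not join 1:1; orphan ids: {sorted(orphans)}")
    df = cohort.merge(features, on="patient_id", validate="one_to_one")
    if feature_columns is None:
        feature_columns = [
            c for c in features.columns if c not in ("patient_id", "image")
        ]
    t = df["time_months"].to_numpy(dtype=float)
    d = df["event"].to_numpy(dtype=int)

    rows, groups = {}, {}
    km_curves = {}
    for name in feature_columns:
        x = df[name].to_numpy(dtype=float)
        try:
            row = prognostics.evaluate_feature(
                x, t, d, n_boot=config.n_boot, seed=config.seed,
                min_group_frac=config.min_group_frac,
            )
        except prognostics.EvaluationError as exc:
            rows[name] = {"error": str(exc)}
            continue
        rows[name] = row
        g = (x > row["cutpoint"]).astype(int)
        groups[name] = g
        curves, lr_p = prognostics.km_summary(g, t, d)
        curves["logrank_p"] = lr_p
        km_curves[name] = curves

    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "feature"

    candidates = pd.DataFrame(groups, index=df.index)
    if candidates.shape[1] >= 2:
        multivariate = prognostics.cox_multivariate(candidates, t, d)
    else:
        multivariate = None
    spearman_rho, spearman_p, constant = prognostics.spearman_matrix(
        df[feature_columns]
    )
    return {
        "report": report,
        "multivariate": multivariate,
        "spearman_rho": spearman_rho,
        "spearman_p": spearman_p,
        "constant_features": constant,
        "km_curves": km_curves,
        "seed": config.seed,
    }


def write_prognosis(result: dict[str, object], out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["report"].to_csv(out / "report.csv")
    result["spearman_rho"].to_csv(out / "spearman_rho.csv")
    result["spearman_p"].to_csv(out / "spearman_p.csv")
    mv = result["multivariate"]
    payload = {
        "seed": result["seed"],
        "constant_features": result["constant_features"],
        "multivariate": None,
    }
    if mv is not None:
        payload["multivariate"] = {
            "entered": mv.entered,
            "dropped_collinear": mv.dropped_collinear,
            "selected": mv.selected.reset_index()
            .rename(columns={"index": "feature", "covariate": "feature"})
            .to_dict(orient="records"),
        }
    (out / "multivariate.json").write_text(json.dumps(payload, indent=2, default=str))
    km_dir = out / "km"
    km_dir.mkdir(exist_ok=True)
    for name, curves in result["km_curves"].items():
        curves.to_csv(km_dir / f"{name}.csv", index=False)
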