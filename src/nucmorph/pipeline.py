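"""Batch scoring and the end-to-end pipeline.

``score_contour``/``score_mask`` compute every enabled irregularity metric
for one nucleus; ``score_batch`` runs them over a directory (images, masks
or contour CSVs, auto-detected) or over in-memory synthetic nuclei, and
returns a tidy per-image score table.  ``full_pipeline`` chains synthesis
(optional), segmentation, scoring and the Friedman + post-hoc statistics
into one reproducible run.

Score column naming is fixed so downstream consumers can rely on it:
``pd_s{span}_{function}`` for the penalty-driven score,
``resid_{mean|median}_{mu|sigma}`` for the residual analyses, and
``ra`` / ``sf`` / ``rd`` for the classic comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .errors import NucmorphError, ParameterError
from .geometry import (
    Contour,
    compute_centroid,
    contour_to_mask,
    extract_contour,
    radial_distances,
)
from .metrics import shape_metrics
from .penalty import PENALTY_TABLE, SPANS, PenaltyConfig, penalty_driven_score
from .residual import mean_residual_analysis, median_residual_analysis
from .segmentation import segment_nucleus
from .stats import significance_table, report_to_frame
from .synthetic import CohortSpec, SyntheticNucleus, generate_cohort

__all__ = ["RunConfig", "score_contour", "score_mask", "score_batch", "full_pipeline"]

log = logging.getLogger("nucmorph")


@dataclass(frozen=True)
class RunConfig:
    """Which scores to compute and how to run the statistics."""

    spans: tuple[int, ...] = SPANS
    functions: tuple[str, ...] = ("linear", "quadratic", "cubic")
    residual_types: tuple[str, ...] = ("mean", "median")
    classic: bool = True
    boundary: str = "wrap"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.spans and self.functions) and not self.residual_types and not self.classic:
            raise ParameterError("at least one metric must be enabled")
        for s in self.spans:
            if s % 2 == 0 or s < 3:
                raise ParameterError("spans must be odd integers >= 3")
        for f in self.functions:
            if f not in PENALTY_TABLE:
                raise ParameterError("unknown penalty function %r" % f)
        for t in self.residual_types:
            if t not in ("mean", "median"):
                raise ParameterError("residual types must be 'mean' or 'median'")
        if not (0.0 <= self.alpha < 1.0):
            raise ParameterError("alpha must lie in [0, 1)")

    @property
    def metric_columns(self) -> list[str]:
        cols = [
            "pd_s%d_%s" % (s, f) for s in self.spans for f in self.functions
        ]
        cols += ["resid_%s_%s" % (t, q) for t in self.residual_types for q in ("mu", "sigma")]
        if self.classic:
            cols += ["ra", "sf", "rd"]
        return cols


def score_contour(
    contour: Contour, config: RunConfig = RunConfig(), mask: np.ndarray | None = None
) -> dict[str, float]:
    """All enabled scores for one nucleus contour.

    The classic metrics need the filled region; when no mask is supplied it
    is reconstructed by filling the contour.
    """
    out: dict[str, float] = {}
    profile = radial_distances(contour, compute_centroid(contour))
    for span in config.spans:
        for fn in config.functions:
            cfg = PenaltyConfig(span=span, function=fn, boundary=config.boundary)
            out["pd_s%d_%s" % (span, fn)] = penalty_driven_score(contour, cfg).pd
    for rtype in config.residual_types:
        res = (
            mean_residual_analysis(profile)
            if rtype == "mean"
            else median_residual_analysis(profile)
        )
        out["resid_%s_mu" % rtype] = res.mu
        out["resid_%s_sigma" % rtype] = res.sigma
    if config.classic:
        if mask is None:
            mask = contour_to_mask(contour)
        sm = shape_metrics(mask, contour)
        out.update(ra=sm.ra, sf=sm.sf, rd=sm.rd)
    return out


def score_mask(mask: np.ndarray, config: RunConfig = RunConfig()) -> dict[str, float]:
    """Scores for a binary nucleus mask (contour traced internally)."""
    return score_contour(extract_contour(mask), config, mask=mask)


def _score_one_file(path: Path, config: RunConfig) -> dict[str, float]:
    if path.suffix.lower() == ".csv":
        return score_contour(nio.read_contour_csv(path), config)
    img = nio.read_image(path)
    if img.ndim == 2:
        vals = np.unique(img)
        if len(vals) <= 2:  # binary mask path
            return score_mask(img > 0, config)
        return score_mask(segment_nucleus(img), config)
    return score_mask(segment_nucleus(img), config)


def score_items(
    items: list[SyntheticNucleus], config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Score in-memory synthetic nuclei into a labeled score table."""
    rows = []
    for item in items:
        row = {"image_id": item.item_id, "label": item.label}
        row.update(score_contour(item.contour, config, mask=item.mask))
        rows.append(row)
    return pd.DataFrame(rows)


def score_batch(
    input_dir: str | Path, config: RunConfig = RunConfig()
) -> tuple[pd.DataFrame, list[dict]]:
    """Score every image/mask/contour file in ``input_dir``.

    Class labels come from a ``manifest.csv`` (columns ``image_id``,
    ``label``) when present, else from first-level subdirectory names.
    Files that fail are collected as error records, not silently dropped.

    Returns ``(scores, errors)``.
    """
    input_dir = Path(input_dir)
    manifest = None
    mpath = input_dir / "manifest.csv"
    if mpath.exists():
        manifest = pd.read_csv(mpath).set_index("image_id")["label"].to_dict()
    files = sorted(
        p
        for p in input_dir.rglob("*")
        if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".csv")
        and p.name != "manifest.csv"
    )
    rows, errors = [], []
    for path in files:
        item_id = path.stem
        label = None
        if manifest is not None:
            label = manifest.get(item_id)
        elif path.parent != input_dir:
            label = path.parent.name
        try:
            row = {"image_id": item_id, "label": label}
            row.update(_score_one_file(path, config))
            rows.append(row)
            log.info("scored %s", path.name)
        except (NucmorphError, OSError, ValueError) as exc:
            errors.append({"image_id": item_id, "file": str(path), "error": str(exc)})
            log.warning("failed %s: %s", path.name, exc)
    return pd.DataFrame(rows), errors


@dataclass(frozen=True)
class PipelineResult:
    scores: pd.DataFrame
    manifest: pd.DataFrame | None
    reports: dict
    summary: pd.DataFrame
    errors: list = field(default_factory=list)


def full_pipeline(
    config: RunConfig = RunConfig(),
    input_dir: str | Path | None = None,
    cohort: CohortSpec | None = None,
    through_segmentation: bool = False,
) -> PipelineResult:
    """simulate (optional) -> segment -> score -> statistics.

    Exactly one of ``input_dir`` (existing files) or ``cohort`` (synthetic
    generation) must be given.  With ``through_segmentation`` the synthetic
    nuclei are rendered to images and re-segmented before scoring instead
    of using their ground-truth masks.
    """
    if (input_dir is None) == (cohort is None):
        raise ParameterError("provide exactly one of input_dir or cohort")
    manifest = None
    errors: list[dict] = []
    if cohort is not None:
        items, manifest = generate_cohort(cohort)
        if through_segmentation:
            from .synthetic import render_image

            rows = []
            for item in items:
                img, _ = render_image(item, cohort.render)
                try:
                    row = {"image_id": item.item_id, "label": item.label}
                    row.update(score_mask(segment_nucleus(img), config))
                    rows.append(row)
                except NucmorphError as exc:
                    errors.append({"image_id": item.item_id, "error": str(exc)})
            scores = pd.DataFrame(rows)
        else:
            scores = score_items(items, config)
    else:
        scores, errors = score_batch(input_dir, config)
    if scores.empty:
        raise NucmorphError("no image produced any scores")
    reports = significance_table(
        scores, config.metric_columns, alpha=config.alpha, seed=config.seed
    )
    return PipelineResult(
        scores=scores,
        manifest=manifest,
        reports=reports,
        summary=report_to_frame(reports),
        errors=errors,
    )
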