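"""CSV ingestion, report serialization and the diagnostic figure.

Input is a comma-separated file with a header row (UTF-8); two columns are
selected by name, rows with missing or non-numeric entries in either are
dropped listwise, and the drop count plus per-column descriptive statistics
(n, mean, sd) are logged so they can be checked against a source study's
reported descriptives.

Reports serialize two ways: a TSV row mirroring the familiar
necessity / sufficiency / difference table layout (three decimals, small
p-values rendered "<0.001", the difference as "mean (SE)"), and JSON at full
precision carrying seeds, technique, the plug-in difference and the guard
flag so a run is exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PairedSample, Technique, ce_fdh_ceiling, compute_scope, cr_fdh_ceiling
from .exceptions import InsufficientDataError, MissingColumnError
from .inference import DEFAULT_ALPHA, DEFAULT_BOOTSTRAP, DEFAULT_PERMUTATIONS, ExtendedReport

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of one analysis run; defaults follow the standard protocol of
    10,000 permutations and 10,000 bootstrap resamples."""

    input: str
    x_column: str
    y_column: str
    technique: Technique = "ce_fdh"
    n_permutations: int = DEFAULT_PERMUTATIONS
    n_bootstrap: int = DEFAULT_BOOTSTRAP
    seed: int | None = None
    alpha: float = DEFAULT_ALPHA
    output_format: str = "tsv"  # tsv | json
    plot: str | None = None


@dataclass(frozen=True)
class CleaningLog:
    n_raw: int
    n_dropped: int
    n_kept: int
    stats: dict  # per-column {n, mean, sd}


def load_sample(path: str | Path, x_column: str, y_column: str
                ) -> tuple[PairedSample, CleaningLog]:
    """Read a two-variable sample from CSV with listwise deletion.

    Raises :class:`MissingColumnError` for absent columns and
    :class:`InsufficientDataError` when fewer than 3 complete rows remain.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (x_column, y_column):
        if col not in df.columns:
            raise MissingColumnError(
                f"column {col!r} not in {list(df.columns)}"
            )
    x = pd.to_numeric(df[x_column], errors="coerce")
    y = pd.to_numeric(df[y_column], errors="coerce")
    keep = x.notna() & y.notna()
    n_raw = len(df)
    n_kept = int(keep.sum())
    if n_kept < 3:
        raise InsufficientDataError(
            f"only {n_kept} complete rows in {path} (need >= 3)"
        )
    xv = x[keep].to_numpy(dtype=float)
    yv = y[keep].to_numpy(dtype=float)
    stats = {
        x_column: {"n": n_kept, "mean": float(xv.mean()), "sd": float(xv.std(ddof=1))},
        y_column: {"n": n_kept, "mean": float(yv.mean()), "sd": float(yv.std(ddof=1))},
    }
    log = CleaningLog(n_raw=n_raw, n_dropped=n_raw - n_kept, n_kept=n_kept, stats=stats)
    logger.info(
        "loaded %s: %d rows, %d dropped listwise; %s: M=%.2f SD=%.2f; "
        "%s: M=%.2f SD=%.2f",
        path, n_raw, log.n_dropped,
        x_column, stats[x_column]["mean"], stats[x_column]["sd"],
        y_column, stats[y_column]["mean"], stats[y_column]["sd"],
    )
    return PairedSample(xv, yv, labels=(x_column, y_column)), log


def write_sample_csv(sample: PairedSample, path: str | Path) -> None:
    """Write a sample to CSV with full float precision (round-trips exactly)."""
    df = pd.DataFrame({sample.labels[0]: sample.x, sample.labels[1]: sample.y})
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def report_to_tsv(report: ExtendedReport) -> str:
    """One table row: d, p for necessity; d, p for sufficiency; 'mean (SE)'
    and p for the bootstrap difference; plus a footer note with the
    interpretation."""
    header = "\t".join([
        "variables", "necessity_d", "necessity_p", "sufficiency_d",
        "sufficiency_p", "difference_d_se", "difference_p",
    ])
    row = "\t".join([
        f"{report.labels[0]} -> {report.labels[1]}",
        f"{report.necessity.d:.3f}",
        format_p(report.necessity_p.p),
        f"{report.sufficiency.d:.3f}",
        format_p(report.sufficiency_p.p),
        f"{report.difference.mean_diff:.3f} ({report.difference.se_diff:.3f})",
        format_p(report.difference.p),
    ])
    lines = [header, row, f"# interpretation: {report.interpretation}"
             f" (guard_ok={str(report.guard_ok).lower()})"]
    for note in report.notes:
        lines.append(f"# note: {note}")
    return "\n".join(lines) + "\n"


def report_to_json(report: ExtendedReport) -> str:
    """Full-precision JSON for exact reproducibility (no timestamps)."""
    payload = {
        "labels": list(report.labels),
        "n": report.n,
        "technique": report.technique,
        "alpha": report.alpha,
        "seed": report.seed,
        "necessity": {
            "d": report.necessity.d,
            "ceiling_zone": report.necessity.ceiling_zone,
            "scope_area": report.necessity.scope_area,
            "p": report.necessity_p.p,
            "n_permutations": report.necessity_p.n_permutations,
        },
        "sufficiency": {
            "d": report.sufficiency.d,
            "ceiling_zone": report.sufficiency.ceiling_zone,
            "scope_area": report.sufficiency.scope_area,
            "p": report.sufficiency_p.p,
            "n_permutations": report.sufficiency_p.n_permutations,
        },
        "difference": {
            "mean_diff": report.difference.mean_diff,
            "se_diff": report.difference.se_diff,
            "z": None if np.isnan(report.difference.z) else report.difference.z,
            "p": report.difference.p,
            "plugin_diff": report.difference.plugin_diff,
            "n_bootstrap": report.difference.n_bootstrap,
            "n_skipped": report.difference.n_skipped,
            "se_zero": report.difference.se_zero,
        },
        "guard_ok": report.guard_ok,
        "interpretation": report.interpretation,
        "notes": list(report.notes),
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def write_report(report: ExtendedReport, path: str | Path | None = None,
                 output_format: str = "tsv") -> str:
    """Serialize a report; write to ``path`` if given, return the text."""
    if output_format == "tsv":
        text = report_to_tsv(report)
    elif output_format == "json":
        text = report_to_json(report)
    else:
        raise ValueError(f"unknown format {output_format!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Diagnostics figure
# ---------------------------------------------------------------------------

def render_diagnostics(sample: PairedSample, report: ExtendedReport,
                       path: str | Path) -> None:
    """Two-panel figure: the scatter with scope rectangle, ceiling and floor,
    and the histogram of bootstrap differences with zero marked.

    Plotting failures are logged and swallowed so a failed figure never
    aborts an analysis.
    """
    try:
        _render(sample, report, path)
    except Exception:  # pragma: no cover - environment-dependent
        logger.exception("diagnostics rendering failed; continuing")


def _render(sample: PairedSample, report: ExtendedReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scope = compute_scope(sample)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 9))

    ax1.scatter(sample.x, sample.y, s=12, alpha=0.6, color="tab:blue")
    ax1.add_patch(plt.Rectangle(
        (scope.x_min, scope.y_min), scope.x_max - scope.x_min,
        scope.y_max - scope.y_min, fill=False, edgecolor="red", lw=1.2))
    _draw_ceiling(ax1, sample, report.technique, color="tab:orange",
                  label="ceiling")
    _draw_floor(ax1, sample, report.technique, color="tab:green",
                label="floor")
    ax1.set_xlabel(sample.labels[0])
    ax1.set_ylabel(sample.labels[1])
    ax1.set_title(
        f"necessity d={report.necessity.d:.3f}, "
        f"sufficiency d={report.sufficiency.d:.3f} ({report.technique})")
    ax1.legend(loc="lower right", fontsize=8)

    diffs = report.difference.differences
    if diffs is not None and len(diffs) > 0:
        ax2.hist(diffs, bins=40, color="tab:gray")
        ax2.axvline(0.0, color="red", lw=1.2)
        ax2.set_xlabel("necessity d − sufficiency d (bootstrap)")
        ax2.set_ylabel("frequency")
        ax2.set_title(
            f"difference {report.difference.mean_diff:.3f} "
            f"(SE {report.difference.se_diff:.3f}), p={format_p(report.difference.p)}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _draw_ceiling(ax, sample: PairedSample, technique: Technique, **kw) -> None:
    scope = compute_scope(sample)
    if technique == "cr_fdh":
        line = cr_fdh_ceiling(sample, scope)
        if line.fallback_step is None:
            xs = np.array([scope.x_min, scope.x_max])
            ax.plot(xs, np.clip(line(xs), scope.y_min, scope.y_max), **kw)
            return
    step = ce_fdh_ceiling(sample, scope)
    xb = np.append(step.breaks, scope.x_max)
    ax.step(xb, np.append(step.levels, step.levels[-1]), where="post", **kw)


def _draw_floor(ax, sample: PairedSample, technique: Technique, **kw) -> None:
    # the floor of (x, y) is the ceiling of the swapped sample, drawn with
    # the axes exchanged back
    swapped = sample.swapped()
    scope = compute_scope(swapped)
    if technique == "cr_fdh":
        line = cr_fdh_ceiling(swapped, scope)
        if line.fallback_step is None:
            ys = np.array([scope.x_min, scope.x_max])  # original y range
            ax.plot(np.clip(line(ys), scope.y_min, scope.y_max), ys, **kw)
            return
    step = ce_fdh_ceiling(swapped, scope)
    yb = np.append(step.breaks, scope.x_max)
    ax.step(np.append(step.levels, step.levels[-1]), yb, where="post", **kw)
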