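"""Reproducible end-to-end pipeline: simulate -> fit -> bootstrap -> correlate.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` substreams (cohort, bootstrap), so any stage
can be reproduced independently.  Every stage's outputs, warnings, and
exclusion counts are recorded in a run manifest serialized next to the
results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import CohortConfig, paper_defaults, simulate_cohort
from .curves import bootstrap_retention, fit_transfer, prevail_time
from .design import OLDER, YOUNG
from .hippocampus import fit_long_term, fit_short_term
from .retention import PARAM_NAMES, fit_retention
from .trends import correlate_trends, individual_trends, slope_vs_followup
from .validate import validate_input_table

logger = logging.getLogger(__name__)

GROUPS = (YOUNG, OLDER)


@dataclass
class RunManifest:
    config_hash: str
    seed: Optional[int]
    package_version: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, status: str, outputs: Optional[list] = None, **extra):
        self.stages[stage] = {"status": status, "outputs": outputs or [], **extra}


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
        # expose derived CI properties (e.g. EffectEstimate)
        for prop in ("ci_low", "ci_high"):
            if prop not in out and hasattr(obj, prop):
                out[prop] = _to_jsonable(getattr(obj, prop))
        return out
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    return obj


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(_to_jsonable(obj), indent=2, sort_keys=True) + "\n")


def config_hash(config: CohortConfig) -> str:
    payload = json.dumps(_to_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: Optional[CohortConfig] = None,
    out_dir: Union[str, Path] = "memtrain_run",
    seed: Optional[int] = None,
    data: Optional[Union[str, Path, pd.DataFrame]] = None,
    n_boot: int = 1000,
    make_plots: bool = False,
) -> RunManifest:
    """Run every analysis stage and write results + report under out_dir.

    With ``data`` given, a user-supplied long-format CSV is analysed
    through the identical code path instead of a simulated cohort.
    """
    from importlib.metadata import version as _v

    config = paper_defaults() if config is None else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = _v("memtrain")
    except Exception:  # not installed (e.g. direct source use)
        pkg_version = "unknown"
    manifest = RunManifest(
        config_hash=config_hash(config), seed=seed, package_version=pkg_version
    )
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    cohort_seed, boot_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)
    )

    truth = None
    if data is None:
        frame, truth = simulate_cohort(config, seed=cohort_seed)
        csv_path = out / "visits.csv"
        cohort_mod.write_visits_csv(frame, csv_path)
        cohort_mod.write_truth_json(truth, out / "truth.json")
        manifest.record(
            "simulate", "completed", [str(csv_path), str(out / "truth.json")],
            n_participants=int(frame["participant_id"].nunique()),
            clamped_fraction=truth["clamped_fraction"],
        )
    else:
        frame = (
            pd.read_csv(data, dtype={"participant_id": str})
            if not isinstance(data, pd.DataFrame)
            else data
        )
        errors = validate_input_table(frame)
        if errors:
            manifest.record("validate", "failed", errors=errors)
            _dump(manifest, out / "manifest.json")
            raise ValueError(f"input table invalid: {errors[:5]}")
        manifest.record("validate", "completed")

    results: dict = {}

    def _stage(name, fn):
        try:
            results[name] = fn()
            manifest.record(name, "completed")
        except Exception as exc:  # record and continue with later stages
            logger.error("stage %s failed: %s", name, exc)
            manifest.record(name, "failed", error=str(exc))
            results[name] = None

    _stage("fit_retention", lambda: fit_retention(frame))
    retention = results["fit_retention"]

    def _bootstrap():
        band = bootstrap_retention(frame, retention, n_boot=n_boot, seed=boot_seed)
        band.to_frame().to_csv(out / "retention_band.csv", index=False)
        _dump(
            {
                "n_boot": band.n_boot,
                "n_dropped": band.n_dropped,
                "seed": band.seed,
                "prevail_years": {g: prevail_time(band, g) for g in GROUPS},
            },
            out / "retention_band.json",
        )
        return band

    if retention is not None:
        _stage("bootstrap", _bootstrap)
    _stage("fit_transfer", lambda: fit_transfer(frame))
    _stage("fit_hippocampus_short", lambda: fit_short_term(frame))
    _stage("fit_hippocampus_long", lambda: fit_long_term(frame))

    def _correlations():
        mem = individual_trends(frame, "memory_score")
        hip = individual_trends(frame, "hippocampus_mm3")
        wp = individual_trends(frame, "wordpair_score")
        pd.concat([mem, hip, wp]).to_csv(out / "individual_trends.csv", index=False)
        corr = {
            "memory_vs_hippocampus_slope": correlate_trends(mem, hip),
            "memory_vs_wordpair_slope": correlate_trends(mem, wp),
            "memory_level_vs_hippocampus_slope": correlate_trends(
                mem, hip, on="intercept"
            ),
            "hippocampus_slope_vs_followup_memory": slope_vs_followup(hip, frame),
            "excluded": {
                "memory": mem.attrs["n_excluded"],
                "hippocampus": hip.attrs["n_excluded"],
                "wordpair": wp.attrs["n_excluded"],
            },
        }
        _dump(corr, out / "correlations.json")
        return corr

    _stage("correlations", _correlations)

    for name in ("fit_retention", "fit_transfer"):
        model = results[name]
        if model is not None:
            _dump(
                {
                    "estimates": model.summary(),
                    "loglik": model.loglik_,
                    "converged": model.converged_,
                    "n_subjects": model.n_subjects_,
                    "n_obs": model.n_obs_,
                    "group_mean_age": model.group_mean_age_,
                },
                out / f"{name}.json",
            )
    if results.get("fit_hippocampus_short") is not None:
        _dump(results["fit_hippocampus_short"], out / "hippocampus_short.json")
    if results.get("fit_hippocampus_long") is not None:
        _dump(results["fit_hippocampus_long"], out / "hippocampus_long.json")

    report = _render_report(config, results, truth, n_boot)
    (out / "report.md").write_text(report)
    manifest.record("report", "completed", [str(out / "report.md")])

    if make_plots:
        try:
            _make_plots(results, out)
            manifest.record("plots", "completed")
        except Exception as exc:
            manifest.record("plots", "failed", error=str(exc))

    _dump(manifest, out / "manifest.json")
    return manifest


def _render_report(config, results, truth, n_boot: int) -> str:
    lines = ["# memtrain run report", ""]
    retention = results.get("fit_retention")
    if retention is not None:
        lines += ["## Retention model (criterion task, words)", ""]
        lines += ["| parameter | estimate | 95% CI | generative truth |",
                  "|---|---|---|---|"]
        for name in PARAM_NAMES:
            est = getattr(retention.params_, name)
            ci = retention.conf_int_.loc[name]
            tr = "" if truth is None else f"{truth['retention'][name]:.3g}"
            lines.append(
                f"| {name} | {est:.3g} | ({ci['low']:.3g}, {ci['high']:.3g}) | {tr} |"
            )
        lines.append("")
    transfer = results.get("fit_transfer")
    if transfer is not None:
        lines += ["## Transfer model (word pairs)", ""]
        lines += ["| parameter | estimate | 95% CI | generative truth |",
                  "|---|---|---|---|"]
        for name in PARAM_NAMES:
            est = getattr(transfer.params_, name)
            ci = transfer.conf_int_.loc[name]
            tr = "" if truth is None else f"{truth['transfer'][name]:.3g}"
            lines.append(
                f"| {name} | {est:.3g} | ({ci['low']:.3g}, {ci['high']:.3g}) | {tr} |"
            )
        lines.append("")
    band = results.get("bootstrap")
    if band is not None:
        lines += [f"## Retention band ({band.n_boot} bootstrap samples)", ""]
        for g in GROUPS:
            pt = prevail_time(band, g)
            flag = " (censored at grid end)" if pt.censored else ""
            lines.append(f"- {g}: effect prevails to {pt.years:.2f} years{flag}")
        lines.append("")
    short = results.get("fit_hippocampus_short")
    if short is not None:
        lines += ["## Hippocampal short-term status effects (mm^3 vs baseline)", ""]
        for label, eff in (("post_train", short.post_train), ("post_rest", short.post_rest)):
            for g in GROUPS:
                e = eff[g]
                lines.append(
                    f"- {g} {label}: {e.estimate:.1f} ({e.ci_low:.1f}, {e.ci_high:.1f})"
                )
        lines.append("")
    long_c = results.get("fit_hippocampus_long")
    if long_c is not None:
        lines += ["## Hippocampal long-term trained-vs-control contrast (mm^3)", ""]
        for g in GROUPS:
            e = long_c.slope_diff_at_horizon[g]
            lines.append(
                f"- {g} at {long_c.horizons[g]:.2f} y: "
                f"{e.estimate:.0f} ({e.ci_low:.0f}, {e.ci_high:.0f})"
            )
        lines.append("")
    corr = results.get("correlations")
    if corr is not None:
        lines += ["## Change-change correlations", ""]
        for key, val in corr.items():
            if key == "excluded":
                continue
            lines.append(
                f"- {key}: r = {val.r:.2f} ({val.ci_low:.2f}, {val.ci_high:.2f}), n = {val.n}"
            )
        lines.append("")
    return "\n".join(lines)


def _make_plots(results, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    band = results.get("bootstrap")
    if band is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        for g, color in zip(GROUPS, ("C0", "C1")):
            ax.plot(band.grid, band.estimate[g], color=color, label=g)
            ax.fill_between(band.grid, band.lower[g], band.upper[g], alpha=0.2, color=color)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("years since training")
        ax.set_ylabel("retained training effect (words)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "retention_curve.png", dpi=150)
        plt.close(fig)
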