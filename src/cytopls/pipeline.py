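"""End-to-end orchestration: clean → filter → scale → fit → orthogonalize →
validate → VIP → report, for a list of planned comparisons.

The default plan encodes the five study designs the package targets on a
2×2 (genotype × treatment) cytokine panel with a continuous metabolic
response:

1. ``genotype_vehicle``  — PLSDA of genotype among vehicle-treated samples
2. ``genotype_abeta``    — PLSDA of genotype among Aβ-treated samples
3. ``treatment_apoe3``   — PLSDA of treatment among APOE3 samples
4. ``treatment_apoe4``   — PLSDA of treatment among APOE4 samples
5. ``plsr_basal_ocr``    — PLSR of the continuous response on all samples

Each comparison emits scores/loadings/VIP tables and a validation JSON, and
the run log carries enough provenance (seeds, config hash, exclusion
fraction) to re-execute bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from . import cleaning, pls, validation
from .panel import CleanedMatrix, PanelDataset, write_cleaned


class PipelineError(ValueError):
    pass


@dataclasses.dataclass
class Comparison:
    """One planned model: a sample filter, a contrast, and validation knobs."""

    name: str
    mode: str  # "plsda" | "plsr"
    contrast: str  # metadata column (plsda) or response column (plsr)
    sample_filter: dict[str, str] | None = None
    L: int | str = "auto"
    L_max: int = 5
    n_permutations: int = validation.DEFAULT_PERMUTATIONS
    n_repeats: int = validation.DEFAULT_REPEATS
    seed: int = 0


@dataclasses.dataclass
class AnalysisPlan:
    comparisons: list[Comparison]
    min_beads: int = cleaning.DEFAULT_MIN_BEADS
    strict_beads: bool = False
    bead_check: bool = True
    min_nonzero_fraction: float = cleaning.DEFAULT_MIN_NONZERO_FRACTION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        doc = yaml.safe_load(Path(path).read_text())
        comps = [Comparison(**c) for c in doc.pop("comparisons")]
        return cls(comparisons=comps, **doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def default_plan(seed: int = 0, **kwargs) -> AnalysisPlan:
    """The five standard comparisons on the 2×2 design plus PLSR."""
    comps = [
        Comparison("genotype_vehicle", "plsda", "genotype", {"treatment": "vehicle"}, seed=seed),
        Comparison("genotype_abeta", "plsda", "genotype", {"treatment": "abeta"}, seed=seed + 1),
        Comparison("treatment_apoe3", "plsda", "treatment", {"genotype": "APOE3"}, seed=seed + 2),
        Comparison("treatment_apoe4", "plsda", "treatment", {"genotype": "APOE4"}, seed=seed + 3),
        Comparison("plsr_basal_ocr", "plsr", "response", None, seed=seed + 4),
    ]
    return AnalysisPlan(comparisons=comps, **kwargs)


def _validate_plan(plan: AnalysisPlan, panel: PanelDataset) -> None:
    cols = set(panel.samples.columns)
    for comp in plan.comparisons:
        if comp.mode not in ("plsda", "plsr"):
            raise PipelineError(f"comparison '{comp.name}': unknown mode {comp.mode!r}")
        if comp.contrast not in cols:
            raise PipelineError(
                f"comparison '{comp.name}': contrast column '{comp.contrast}' "
                f"not in metadata columns {sorted(cols)}"
            )
        for col in (comp.sample_filter or {}):
            if col not in cols:
                raise PipelineError(
                    f"comparison '{comp.name}': filter column '{col}' "
                    f"not in metadata columns {sorted(cols)}"
                )


def _comparison_subset(panel_samples, cleaned: CleanedMatrix, comp: Comparison):
    meta = panel_samples
    mask = meta.index == meta.index  # all True
    for col, val in (comp.sample_filter or {}).items():
        mask &= meta[col] == val
    sub = meta[mask]
    y = sub[comp.contrast]
    if comp.mode == "plsr":
        sub = sub[y.notna()]
        y = y[y.notna()].astype(float)
    X = cleaned.values.loc[sub.index]
    if len(X) == 0:
        raise PipelineError(f"comparison '{comp.name}': sample filter matched no samples")
    return X, y


def _max_feasible_L(comp: Comparison, X, y) -> int:
    n = len(X)
    if comp.mode == "plsda":
        counts = y.value_counts()
        n_train = sum(c - max(1, round(c / 3)) for c in counts)
    else:
        n_train = n - max(1, round(n / 3))
    return max(1, min(comp.L_max, n_train - 1, X.shape[1]))


def run_comparison(comp: Comparison, cleaned: CleanedMatrix, samples, out_dir: Path) -> dict:
    X, y = _comparison_subset(samples, cleaned, comp)
    mode = "discriminant" if comp.mode == "plsda" else "regression"
    lv_table = None
    if comp.L == "auto":
        sel = validation.select_num_lvs(
            X, y, _max_feasible_L(comp, X, y), mode=mode,
            n_repeats=comp.n_repeats, seed=comp.seed,
        )
        L = sel.selected
        lv_table = sel.table
    else:
        L = int(comp.L)
    result = validation.permutation_confidence(
        X, y, L, mode=mode, n_permutations=comp.n_permutations,
        n_repeats=comp.n_repeats, seed=comp.seed,
    )

    scaler = pls.zscore(X)
    y_fit = y.to_numpy() if mode == "regression" else y
    model = pls.fit_pls(scaler, y_fit, L, mode=mode)
    model = pls.orthogonalize_lv1(model)
    vip = pls.vip_scores(model)

    out_dir.mkdir(parents=True, exist_ok=True)
    pls.scores_table(model, X.index, groups=y).to_csv(out_dir / "scores.csv")
    pls.loadings_table(model, vip).to_csv(out_dir / "loadings.csv")
    pls.save_model(model, scaler, out_dir / "model.json")
    report = {
        "name": comp.name,
        "mode": comp.mode,
        "contrast": comp.contrast,
        "sample_filter": comp.sample_filter,
        "n_samples": int(len(X)),
        "n_analytes": int(X.shape[1]),
        "L": L,
        "metric_name": result.metric_name,
        "cv_value": result.cv_value,
        "confidence": result.confidence,
        "null_distribution": result.null_distribution.tolist(),
        "vip_above_1": vip.above_average(),
        "seed": comp.seed,
        "summary": result.summary(),
    }
    if lv_table is not None:
        report["lv_selection"] = lv_table.to_dict(orient="records")
    (out_dir / "validation.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_plan(panel: PanelDataset, plan: AnalysisPlan, out_dir: str | Path) -> dict:
    """Execute every comparison of the plan; a failing comparison is reported
    with a named-stage diagnostic and the remaining comparisons proceed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _validate_plan(plan, panel)

    cleaned = cleaning.clean_panel(
        panel, min_beads=plan.min_beads, strict_beads=plan.strict_beads,
        bead_check=plan.bead_check,
    )
    cleaned = cleaning.filter_low_prevalence(cleaned, plan.min_nonzero_fraction)
    write_cleaned(cleaned, out / "cleaned")

    reports: dict[str, dict] = {}
    for comp in plan.comparisons:
        try:
            reports[comp.name] = run_comparison(comp, cleaned, panel.samples, out / comp.name)
        except Exception as exc:  # other comparisons proceed
            reports[comp.name] = {"name": comp.name, "error": f"{type(exc).__name__}: {exc}"}

    log = {
        "config_hash": plan.config_hash(),
        "fraction_excluded": cleaned.fraction_excluded,
        "n_exclusions": int(len(cleaned.exclusions)),
        "dropped_analytes": cleaned.dropped_analytes,
        "comparisons": {
            name: {k: v for k, v in rep.items() if k != "null_distribution"}
            for name, rep in reports.items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return reports
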