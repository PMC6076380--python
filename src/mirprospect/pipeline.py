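"""End-to-end orchestration: normalize -> diffexp -> enrich -> confound ->
classify -> power, from a single config with one global seed.

Every stochastic stage receives a sub-seed derived deterministically from the
global seed, so two runs of the same config produce byte-identical output
files. On a stage failure the outputs already written are renamed with a
``.partial`` suffix and a :class:`~mirprospect.exceptions.PipelineError`
naming the stage is raised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as io_mod
from .classify import ClassifierConfig, cross_validated_fit, pairwise_group_classification
from .confound import (
    anova_screen,
    cohort_balance_tests,
    correlation_screen,
    history_group_analysis,
    validate_annotation,
)
from .diffexp import CohortSplit, run_diffexp
from .enrich import enrich_cutoff_free, enrich_set_based
from .exceptions import ConfigurationError, PipelineError, StructuralError
from .matrix import ExpressionMatrix
from .normalize import normality_screen, preprocess
from .power import solve_effect_size
from .synth import SynthConfig, generate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "big") % 2**32]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Inputs, options and output location of one pipeline run.

    Either the three input paths or ``synth`` must be provided. The default
    classifier grid here is deliberately lighter than the full search grid so
    the end-to-end run stays interactive; pass an explicit ``classifier`` for
    the full search.
    """

    expression_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    synth: SynthConfig | None = None
    output_dir: str = "mirprospect_out"
    seed: int = 0
    # normalization
    background: float = 0.0
    floor: float = 1.0
    log_before_normalize: bool = False
    # tests
    welch: bool = True
    exact_wilcoxon_threshold: int = 12
    alpha: float = 0.05
    # enrichment
    ranking_criterion: str = "auc"
    enrichment_tail: str = "ge"
    # classification
    classifier: ClassifierConfig | None = None
    group_pairs: tuple[tuple[int, int], ...] = ((1, 4), (2, 3))
    # power
    power_specs: tuple[tuple[int, int, float, float], ...] = (
        (33, 33, 0.05, 0.95),
        (33, 500, 0.05, 0.95),
    )
    run_normality_screen: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "classifier" in raw and raw["classifier"] is not None:
            raw["classifier"] = ClassifierConfig(**raw["classifier"])
        if "group_pairs" in raw and raw["group_pairs"] is not None:
            raw["group_pairs"] = tuple(tuple(p) for p in raw["group_pairs"])
        if "power_specs" in raw and raw["power_specs"] is not None:
            raw["power_specs"] = tuple(tuple(p) for p in raw["power_specs"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("output_dir")  # where results land does not change what they are
        payload = json.dumps(fields, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineResult:
    """In-memory results and the paths of everything written."""

    diffexp: object
    enrichment_cutoff_free: pd.DataFrame | None
    enrichment_set_based: pd.DataFrame | None
    balance: pd.DataFrame
    history: object
    classifier: object
    pairwise: pd.DataFrame | None
    power: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _default_pipeline_classifier(seed: int) -> ClassifierConfig:
    return ClassifierConfig(
        feature_grid=(2, 3, 5, 8, 13), leaves_grid=(31,), trees_grid=(100,), seed=seed
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index_label: str | None = None) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label,
                     lineterminator="\n")
        written[name] = path

    stage = "load"
    try:
        if config.synth is not None:
            ds = generate(config.synth)
            raw, annotation, categories = ds.expression, ds.annotation, ds.categories
        else:
            if not config.expression_path or not config.annotation_path:
                raise ConfigurationError(
                    "provide expression_path and annotation_path, or a synth config"
                )
            raw = io_mod.read_expression(config.expression_path)
            annotation = io_mod.read_annotation(config.annotation_path)
            if config.gmt_path:
                gmt = Path(config.gmt_path)
                if not gmt.exists():
                    raise ConfigurationError(f"GMT file not found: {gmt}")
                categories = io_mod.read_gmt(gmt)
            else:
                categories = None
        validate_annotation(annotation)
        missing = sorted(set(annotation["sample_id"]) ^ set(raw.sample_ids))
        if missing:
            raise StructuralError(f"annotation/expression sample mismatch: {missing[:5]}")

        stage = "normalize"
        mat = preprocess(
            raw,
            background=config.background,
            floor=config.floor,
            log_before_normalize=config.log_before_normalize,
        )
        if config.run_normality_screen:
            emit("normality", normality_screen(mat, alpha=config.alpha).table, "miRNA")

        stage = "diffexp"
        split = CohortSplit.from_annotation(annotation)
        de = run_diffexp(
            mat,
            split,
            welch=config.welch,
            exact_threshold=config.exact_wilcoxon_threshold,
            alpha=config.alpha,
        )
        emit("diffexp", de.table, "miRNA")
        emit("volcano_cohort", de.volcano_table(), "miRNA")

        stage = "enrich"
        enr_cf = enr_set = None
        if categories:
            enr_cf = enrich_cutoff_free(
                de.table, categories, criterion=config.ranking_criterion,
                tail=config.enrichment_tail,
            )
            significant = de.significant("t").index.tolist()
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                enr_set = enrich_set_based(significant, de.table.index.tolist(), categories)
            emit("enrichment_cutoff_free", enr_cf, "name")
            emit("enrichment_set_based", enr_set, "name")

        stage = "confound"
        ann_idx = annotation.set_index("sample_id")
        balance = cohort_balance_tests(annotation, seed=stage_seed(config.seed, "balance"))
        emit("balance", balance, "covariate")
        screens = []
        for cov in ("age", "packyears"):
            scr = correlation_screen(mat, ann_idx[cov])
            scr.insert(0, "covariate", cov)
            scr.insert(1, "kind", "pearson")
            screens.append(scr.rename(columns={"r": "statistic"}))
        for cov in ("gender", "smoking"):
            scr = anova_screen(mat, ann_idx[cov])
            scr.insert(0, "covariate", cov)
            scr.insert(1, "kind", "anova")
            screens.append(scr.rename(columns={"F": "statistic"}))
        emit("confounders", pd.concat(screens), "miRNA")
        history = history_group_analysis(mat, annotation, welch=config.welch)
        if history.anova is not None:
            emit("history_anova", history.anova, "miRNA")
        if history.extreme is not None:
            emit("diffexp_groups_1_vs_4", history.extreme.table, "miRNA")
            emit("volcano_groups_1_vs_4", history.extreme.volcano_table(), "miRNA")

        stage = "classify"
        clf_config = config.classifier or _default_pipeline_classifier(
            stage_seed(config.seed, "classify")
        )
        labels = (ann_idx.loc[mat.sample_ids, "cohort"] == "case").astype(int).to_numpy()
        clf = cross_validated_fit(mat, labels, clf_config)
        clf_row = pd.DataFrame(
            [
                {
                    "comparison": "cohort1_vs_cohort2",
                    "n_a": clf.n1,
                    "n_b": clf.n2,
                    "k": clf.best_params["k"],
                    "num_leaves": clf.best_params["num_leaves"],
                    "n_estimators": clf.best_params["n_estimators"],
                    "accuracy_pct": clf.accuracy,
                    "auc_pct": clf.auc,
                    "signature": ",".join(clf.signature),
                }
            ]
        )
        pairwise = None
        group_sizes = ann_idx["group"].value_counts()
        usable_pairs = [
            p
            for p in config.group_pairs
            if group_sizes.get(p[0], 0) >= clf_config.n_folds
            and group_sizes.get(p[1], 0) >= clf_config.n_folds
        ]
        if usable_pairs:
            pairwise, _ = pairwise_group_classification(mat, annotation, usable_pairs, clf_config)
        emit(
            "classification",
            pd.concat(
                [clf_row]
                + (
                    [
                        pairwise.assign(
                            comparison=[f"group{a}_vs_group{b}" for a, b in usable_pairs]
                        ).drop(columns=["group_a", "group_b"])
                    ]
                    if pairwise is not None
                    else []
                ),
                ignore_index=True,
            ),
        )

        stage = "power"
        power_rows = [
            {
                "n1": n1,
                "n2": n2,
                "alpha": alpha,
                "power": pw,
                "effect_size_d": solve_effect_size(n1, n2, alpha, pw),
            }
            for n1, n2, alpha, pw in config.power_specs
        ]
        power_table = pd.DataFrame(power_rows)
        emit("power", power_table)

        stage = "manifest"
        import lightgbm
        import scipy
        import sklearn

        manifest = {
            "package": {"mirprospect": __version__},
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
                "lightgbm": lightgbm.__version__,
            },
            "seed": config.seed,
            "config_sha256": config.config_hash(),
            "outputs": {k: v.name for k, v in written.items()},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = manifest_path
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        for path in written.values():
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineError(stage, exc) from exc

    return PipelineResult(
        diffexp=de,
        enrichment_cutoff_free=enr_cf,
        enrichment_set_based=enr_set,
        balance=balance,
        history=history,
        classifier=clf,
        pairwise=pairwise,
        power=power_table,
        paths=written,
    )
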