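"""Configuration-driven orchestration of the three-stage analysis.

Stage i   (``vbcm_raw``): each connected-speech measure is entered separately
          into a VBCM, with and without the lesion-volume covariate.
Stage ii  (``speech_pca`` [+ ``vbcm_factors``]): rotated PCA of the four
          speech measures; the two factor scores entered simultaneously.
Stage iii (``omnibus_pca`` [+ ``vbcm_factors``]): rotated PCA of the full
          battery; the four factor scores entered simultaneously with the
          volume covariate.

Behavioural stages run on the packaged cohort (or any scores TSV); imaging
stages need volumes and masks, which at desk scale come from the synthetic
cohort generator.  Every run writes its tables, NIfTI maps and a JSON report
carrying the package version, seed, configuration (including defaults that
were applied implicitly) and a config hash, so that rerunning a stage with
unchanged inputs reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SPEECH_MEASURES, lesion_volumes, load_cohort
from .factors import VarimaxPCA, fit_pca
from .fluency import measures_table, percent_normalize, read_transcript_file
from .synthetic import SyntheticSpec, default_paper_like_spec, generate_cohort
from .vbcm import (
    VBCMConfig,
    default_analysis_mask,
    overlap_map,
    save_volume,
    vbcm_analysis,
    write_cluster_table,
)

ALL_STAGES = ("fluency", "speech_pca", "omnibus_pca", "vbcm_raw", "vbcm_factors")


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Exactly one input source is used: ``scores_tsv`` (or the packaged cohort
    when it is None and ``synthetic`` is False) versus a generated synthetic
    cohort.
    """

    stages: tuple[str, ...] = ("speech_pca", "omnibus_pca")
    scores_tsv: str | None = None
    transcripts_dir: str | None = None
    synthetic: bool = False
    synthetic_spec: SyntheticSpec | None = None
    vbcm: VBCMConfig = field(default_factory=VBCMConfig)
    output_dir: str = "pcavbcm_out"
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic and self.scores_tsv:
            raise ValueError("set either a scores table or synthetic, not both")
        needs_images = {"vbcm_raw", "vbcm_factors"} & set(self.stages)
        if needs_images and not self.synthetic:
            raise ValueError(
                f"stages {sorted(needs_images)} need image data; "
                "only the synthetic source provides volumes at desk scale"
            )
        if "fluency" in self.stages and not self.transcripts_dir:
            raise ValueError("the fluency stage needs a transcripts directory")
        if "vbcm_factors" in self.stages and not (
            {"speech_pca", "omnibus_pca"} & set(self.stages)
        ):
            raise ValueError("vbcm_factors needs a PCA stage before it")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "vbcm" in raw:
            raw["vbcm"] = VBCMConfig(**raw["vbcm"])
        if raw.pop("synthetic_spec", None) is not None:
            raise ValueError("custom synthetic specs are configured in code")
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("output_dir")  # where outputs land must not change what they are
        spec = d.pop("synthetic_spec")
        if spec is not None:
            d["synthetic_spec"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in spec.items()
                if not isinstance(v, dict)
            }
        return json.loads(json.dumps(d, default=str))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_pca(model: VarimaxPCA, index, out: Path, name: str) -> dict:
    loadings = model.loadings_frame()
    scores = model.scores_frame(index=index)
    loadings.to_csv(out / f"{name}_loadings.tsv", sep="\t", float_format="%.6f")
    scores.to_csv(out / f"{name}_scores.tsv", sep="\t", float_format="%.6f")
    summary = {
        "n_components": model.n_components_,
        "eigenvalues": [round(float(v), 6) for v in model.eigenvalues_],
        "variance_fraction_unrotated": [
            round(float(v), 6) for v in model.variance_fraction_
        ],
        "total_variance_fraction": round(model.total_variance_fraction_, 6),
    }
    (out / f"{name}_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_hash": _config_hash(config),
        "applied_defaults": {
            "vbcm": dataclasses.asdict(VBCMConfig()),
            "stages_available": list(ALL_STAGES),
        },
        "stages": {},
    }

    cohort = None
    if config.synthetic:
        spec = config.synthetic_spec or default_paper_like_spec()
        cohort = generate_cohort(spec, config.seed)
        scores = cohort.behaviour
        volumes_vec = pd.Series(cohort.lesion_volumes, index=scores.index)
    elif config.scores_tsv:
        scores = pd.read_csv(config.scores_tsv, sep="\t", index_col=0)
        volumes_vec = None
    else:
        _, scores = load_cohort()
        volumes_vec = lesion_volumes()

    models: dict[str, VarimaxPCA] = {}
    log_lines: list[str] = []
    for stage in [s for s in ALL_STAGES if s in config.stages]:
        t0 = time.perf_counter()
        info: dict = {}
        if stage == "fluency":
            paths = sorted(Path(config.transcripts_dir).glob("*.cha")) + sorted(
                Path(config.transcripts_dir).glob("*.txt")
            )
            transcripts = [read_transcript_file(p) for p in paths]
            raw = measures_table(transcripts)
            raw.to_csv(out / "fluency_raw.tsv", sep="\t", float_format="%.4f")
            keep = [c for c in ["wpm", "ttr", "mlu", "tokens"] if raw[c].max() > 0]
            pct = percent_normalize(raw[keep], mode="cohort_max")
            pct.to_csv(out / "fluency_percent.tsv", sep="\t", float_format="%.2f")
            info = {"n_transcripts": len(transcripts)}
        elif stage == "speech_pca":
            cols = [c for c in SPEECH_MEASURES if c in scores.columns]
            if len(cols) < len(SPEECH_MEASURES) and not config.synthetic:
                raise ValueError("score table lacks the speech measures")
            sub = scores[cols] if cols else scores.iloc[:, -4:]
            models["speech"] = fit_pca(sub)
            info = _write_pca(models["speech"], scores.index, out, "speech_pca")
        elif stage == "omnibus_pca":
            models["omnibus"] = fit_pca(scores)
            info = _write_pca(models["omnibus"], scores.index, out, "omnibus_pca")
        elif stage == "vbcm_raw":
            info = _run_vbcm(
                cohort,
                scores[[c for c in SPEECH_MEASURES if c in scores.columns]]
                if not config.synthetic
                else scores.iloc[:, -4:],
                volumes_vec,
                config,
                out / "vbcm_raw",
                one_at_a_time=True,
            )
        elif stage == "vbcm_factors":
            model = models.get("omnibus") or models["speech"]
            fscores = model.scores_frame(index=scores.index)
            info = _run_vbcm(
                cohort, fscores, volumes_vec, config, out / "vbcm_factors"
            )
        report["stages"][stage] = {"info": info}
        log_lines.append(f"{stage}: {time.perf_counter() - t0:.3f} s")

    # wall times go to the log, not the report, so that reruns with the same
    # inputs and seed produce byte-identical reports
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _run_vbcm(
    cohort, regressors: pd.DataFrame, volumes_vec, config: RunConfig, out: Path,
    one_at_a_time: bool = False,
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    brain = spec.template() > 0
    amask = default_analysis_mask(cohort.masks, brain, config.vbcm.min_lesioned)
    save_volume(
        overlap_map(cohort.masks).astype(float), spec.affine(), out / "overlap.nii"
    )
    info: dict = {"analysis_mask_voxels": int(amask.sum())}
    groups = (
        [regressors[[c]] for c in regressors.columns]
        if one_at_a_time
        else [regressors]
    )
    for block in groups:
        res = vbcm_analysis(
            cohort.volumes,
            block,
            volumes_vec.to_numpy(float),
            amask,
            config.vbcm,
        )
        for variant in ("with_volume", "without_volume"):
            for fac, r in res[variant].items():
                stem = f"{fac}_{variant}"
                save_volume(r["t"], spec.affine(), out / f"{stem}_t.nii")
                write_cluster_table(r["clusters"], out / f"{stem}_clusters.tsv")
                n_sig = int((r["clusters"].p_fwe < config.vbcm.fwe_alpha).sum())
                info[stem] = {
                    "clusters": int(len(r["clusters"])),
                    "significant": n_sig,
                }
        save_volume(res["volume_map"]["t"], spec.affine(), out / "lesion_volume_t.nii")
    return info


# ---------------------------------------------------------------------------
# individual cases

def case_report(
    patient_id: str,
    factor_scores: pd.DataFrame,
    executive_factor: str = "F3",
    quanta_factor: str = "F4",
    median_to_lower: bool = True,
) -> dict:
    """Place one patient relative to the cohort.

    The cohort is median-split on the executive factor (with an odd cohort
    the median patient joins the lower half by default); within each half the
    extreme speech-quanta patients are flagged.  Ties at the median are
    reported, not silently resolved.
    """
    if patient_id not in factor_scores.index:
        raise KeyError(f"unknown patient {patient_id!r}")
    exe = factor_scores[executive_factor]
    med = float(exe.median())
    n = len(exe)
    if n < 2:
        return {
            "patient_id": patient_id,
            "scores": factor_scores.loc[patient_id].to_dict(),
            "degenerate": "cohort too small for a median split",
        }
    if median_to_lower:
        high = exe > med
    else:
        high = exe >= med
    ties = exe.index[exe == med].tolist() if (exe == med).sum() > 1 else []
    group = "high_executive" if high[patient_id] else "low_executive"
    half = factor_scores.loc[high == high[patient_id], quanta_factor]
    return {
        "patient_id": patient_id,
        "scores": factor_scores.loc[patient_id].round(3).to_dict(),
        "executive_median": round(med, 3),
        "group": group,
        "group_size": int(len(half)),
        "is_group_min_quanta": bool(half.idxmin() == patient_id),
        "is_group_max_quanta": bool(half.idxmax() == patient_id),
        "median_ties": ties,
    }
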