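"""End-to-end analysis pipeline.

read/simulate → dichotomize → composition layers → triad censuses →
rural/urban aggregation → risk classification, chi-square, cross-layer
correlations with power → report.

The report is fully deterministic for a fixed config and inputs; every
number in it is the output of one library operation, and setting-level
census rows are exact componentwise sums of the classroom rows also present.
Degenerate cases (zero-variance correlation vectors, zero-margin tables) are
collected as warnings, never silently dropped and never fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dichotomize import LEVELS, DichotomizedLayers, IntensityThresholds, dichotomize_all
from .errors import DegenerateInputError, TriadscopeError, UsageError
from .io import (
    read_contact_matrix,
    read_network,
    read_roster,
    write_network,
    write_roster,
    write_contact_matrix,
)
from .layers import consumption_layer, homophilous_subnetwork, stratified_census
from .model import Actor, AuditResponse, BinaryNetwork, ContactMatrix
from .simulate import GeneratorConfig, SyntheticStudy, generate_study, load_preset
from .stats import (
    DEFAULT_AUDIT_THRESHOLD,
    benjamini_hochberg,
    chi_square,
    risk_proportions,
    score_audit,
    transitive_profile_correlation,
)
from .triads import (
    DEFAULT_SCHEME,
    TRIAD_TYPES,
    TransitivityScheme,
    TriadCensus,
    aggregate_censuses,
    census,
    census_proportions,
    three_way_scheme,
)

LAYER_NAMES = ("minimum", "intermediate", "maximum", "gender_homophilous", "consumption")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; loadable from YAML via :meth:`from_yaml`."""

    preset: str | None = "paper_shaped"
    seed: int = 0
    input_dir: str | None = None          # roster.csv + contact_/nominations_ per classroom
    thresholds: IntensityThresholds = field(default_factory=IntensityThresholds)
    scheme_name: str = "default"          # default | three_way
    composition_attribute: str = "gender"
    restrict_to_contact: bool = False
    symmetrize_consumption: bool = False
    audit_threshold: int = DEFAULT_AUDIT_THRESHOLD
    alpha: float = 0.05
    correlation_mode: str = "node_profile"
    power_method: str = "exact"
    chi_continuity: bool = False
    bh_adjust: bool = False
    out_dir: str | None = None

    def scheme(self) -> TransitivityScheme:
        if self.scheme_name == "default":
            return DEFAULT_SCHEME
        if self.scheme_name == "three_way":
            return three_way_scheme()
        raise UsageError(f"unknown scheme {self.scheme_name!r}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["thresholds"] = dataclasses.asdict(self.thresholds)
        payload.pop("out_dir")  # where the report lands is not part of the analysis
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        params = yaml.safe_load(Path(path).read_text()) or {}
        params.update({k: v for k, v in overrides.items() if v is not None})
        thr = params.pop("thresholds", None)
        cfg = cls(**params)
        if thr:
            cfg.thresholds = IntensityThresholds(**thr)
        return cfg


@dataclass
class ClassroomResult:
    classroom: str
    setting: str
    n_actors: int
    layers: dict[str, BinaryNetwork]
    censuses: dict[str, TriadCensus]
    stratified: dict[str, dict[str, int]]  # stratum label -> {type: count}


@dataclass
class AnalysisReport:
    config: PipelineConfig
    classrooms: list[ClassroomResult]
    setting_censuses: dict[tuple[str, str], TriadCensus]  # (setting, layer) -> census
    risk_overall: pd.DataFrame
    risk_by_gender: pd.DataFrame
    risk_by_setting: pd.DataFrame
    chi_square_results: dict[str, dict]
    correlations: pd.DataFrame
    warnings: list[str]
    provenance: dict

    def to_json_dict(self) -> dict:
        def census_dict(c: TriadCensus) -> dict:
            return {
                "counts": c.counts, "n_actors": list(c.sizes), "total": c.total,
                "transitive_total": c.transitive_total,
                "intransitive_total": c.intransitive_total,
                "vacuous_total": c.vacuous_total,
                "transitive_share": c.transitive_share,
            }

        return {
            "provenance": self.provenance,
            "classrooms": [
                {
                    "classroom": r.classroom, "setting": r.setting,
                    "n_actors": r.n_actors,
                    "censuses": {layer: census_dict(c) for layer, c in r.censuses.items()},
                    "stratified_gender_census": r.stratified,
                }
                for r in self.classrooms
            ],
            "setting_censuses": {
                f"{setting}/{layer}": census_dict(c)
                for (setting, layer), c in sorted(self.setting_censuses.items())
            },
            "risk": {
                "overall": self.risk_overall.to_dict(orient="records"),
                "by_gender": self.risk_by_gender.to_dict(orient="records"),
                "by_setting": self.risk_by_setting.to_dict(orient="records"),
                "chi_square": self.chi_square_results,
            },
            "correlations": self.correlations.to_dict(orient="records"),
            "warnings": self.warnings,
        }


def _load_study(cfg: PipelineConfig) -> SyntheticStudy:
    if cfg.input_dir is not None:
        root = Path(cfg.input_dir)
        actors, audits = read_roster(root / "roster.csv")
        matrices: dict[str, ContactMatrix] = {}
        nominations: dict[str, BinaryNetwork] = {}
        for label in sorted({a.classroom for a in actors}):
            matrices[label] = read_contact_matrix(
                root / f"contact_{label}.csv", classroom=label
            )
            nominations[label] = read_network(
                root / f"nominations_{label}.csv", classroom=label, layer="consumption"
            )
        gen = GeneratorConfig(seed=cfg.seed)
        return SyntheticStudy(
            actors=actors, audits=audits, contact_matrices=matrices,
            nomination_networks=nominations, true_params=gen,
        )
    preset = cfg.preset or "paper_shaped"
    return generate_study(load_preset(preset, seed=cfg.seed))


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write a study in the exact on-disk formats the readers define."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    write_roster(study.actors, study.audits, root / "roster.csv")
    for label, matrix in study.contact_matrices.items():
        write_contact_matrix(matrix, root / f"contact_{label}.csv")
        write_network(study.nomination_networks[label], root / f"nominations_{label}.csv")


def run_pipeline(cfg: PipelineConfig | None = None) -> AnalysisReport:
    cfg = cfg or PipelineConfig()
    scheme = cfg.scheme()
    study = _load_study(cfg)
    warnings: list[str] = []

    setting_of = {}
    classrooms: list[ClassroomResult] = []
    for label, matrix in study.contact_matrices.items():
        try:
            actors = [a for a in study.actors if a.classroom == label]
            setting = actors[0].setting
            setting_of[label] = setting
            intensity: DichotomizedLayers = dichotomize_all(matrix, cfg.thresholds)
            layers: dict[str, BinaryNetwork] = dict(zip(LEVELS, intensity))
            layers["gender_homophilous"] = homophilous_subnetwork(
                intensity.minimum, actors, cfg.composition_attribute
            )
            layers["consumption"] = consumption_layer(
                study.nomination_networks[label],
                contact=intensity.minimum,
                restrict_to_contact=cfg.restrict_to_contact,
                symmetrize=cfg.symmetrize_consumption,
            )
            censuses = {name: census(net, scheme) for name, net in layers.items()}
            strat = stratified_census(
                intensity.minimum, actors, cfg.composition_attribute, scheme
            )
            classrooms.append(ClassroomResult(
                classroom=label, setting=setting, n_actors=matrix.n_actors,
                layers=layers, censuses=censuses,
                stratified={
                    "/".join(str(v) for v in key): dict(c.counts)
                    for key, c in strat.strata.items()
                },
            ))
        except TriadscopeError as exc:
            raise type(exc)(f"classroom {label!r}, census stage: {exc}") from exc

    setting_censuses: dict[tuple[str, str], TriadCensus] = {}
    for setting in sorted({s for s in setting_of.values()}):
        rooms = [r for r in classrooms if r.setting == setting]
        for layer in LAYER_NAMES:
            setting_censuses[(setting, layer)] = aggregate_censuses(
                [r.censuses[layer] for r in rooms]
            )

    # risk classification and association tests
    risks = [score_audit(resp, cfg.audit_threshold) for resp in study.audits]
    risk_overall = risk_proportions(risks)
    risk_by_gender = risk_proportions(risks, actors=study.actors, by="gender")
    risk_by_setting = risk_proportions(risks, actors=study.actors, by="setting")
    chi_results: dict[str, dict] = {}
    for name, table_df in (("gender_x_risk", risk_by_gender), ("setting_x_risk", risk_by_setting)):
        table = table_df[["at_risk", "no_risk"]].to_numpy()
        try:
            res = chi_square(table, continuity=cfg.chi_continuity)
            chi_results[name] = {
                "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
                "continuity_corrected": res.continuity_corrected,
            }
        except (DegenerateInputError, UsageError) as exc:
            warnings.append(f"chi-square {name}: {exc}")

    # cross-layer correlations, one row per classroom and comparison layer
    rows = []
    for r in classrooms:
        for other in ("minimum", "gender_homophilous"):
            try:
                lc = transitive_profile_correlation(
                    r.layers["consumption"], r.layers[other], scheme,
                    mode=cfg.correlation_mode, alpha=cfg.alpha,
                    power_method=cfg.power_method,
                )
                rows.append({
                    "classroom": r.classroom, "setting": r.setting,
                    "versus_layer": other, "mode": lc.vector_mode,
                    "r": lc.r, "n": lc.n, "p_value": lc.p_value, "power": lc.power,
                })
            except (DegenerateInputError, UsageError) as exc:
                warnings.append(f"correlation {r.classroom}/{other}: {exc}")
    correlations = pd.DataFrame(
        rows, columns=["classroom", "setting", "versus_layer", "mode", "r", "n", "p_value", "power"]
    )
    if cfg.bh_adjust and len(correlations):
        correlations["p_bh"] = benjamini_hochberg(correlations["p_value"])

    report = AnalysisReport(
        config=cfg, classrooms=classrooms, setting_censuses=setting_censuses,
        risk_overall=risk_overall, risk_by_gender=risk_by_gender,
        risk_by_setting=risk_by_setting, chi_square_results=chi_results,
        correlations=correlations, warnings=warnings,
        provenance={
            "config_hash": cfg.config_hash(), "seed": cfg.seed,
            "version": __version__, "audit_threshold": cfg.audit_threshold,
            "source": cfg.input_dir or f"preset:{cfg.preset or 'paper_shaped'}",
        },
    )
    if cfg.out_dir is not None:
        write_report(report, cfg.out_dir)
    return report


def censuses_frame(report: AnalysisReport) -> pd.DataFrame:
    """Long-format census table: one row per (classroom|setting, layer, type)."""
    rows = []

    def add(owner: str, setting: str, c: TriadCensus, layer: str) -> None:
        props = (
            census_proportions(c) if c.total else {code: float("nan") for code in TRIAD_TYPES}
        )
        for code in TRIAD_TYPES:
            rows.append({
                "unit": owner, "setting": setting, "layer": layer, "triad_type": code,
                "count": c.counts[code], "percentage": props[code],
                "partition": c.scheme.partition(code),
            })

    for r in report.classrooms:
        for layer, c in r.censuses.items():
            add(r.classroom, r.setting, c, layer)
    for (setting, layer), c in sorted(report.setting_censuses.items()):
        add(f"setting:{setting}", setting, c, layer)
    return pd.DataFrame(rows)


def compare_settings(report: AnalysisReport) -> pd.DataFrame | None:
    """Rural-vs-urban contrast: risk shares and transitive counts per layer."""
    settings = sorted({r.setting for r in report.classrooms})
    if len(settings) < 2:
        report.warnings.append("compare_settings: only one setting present; contrast skipped")
        return None
    rows = []
    for _, row in report.risk_by_setting.iterrows():
        rows.append({
            "quantity": "risk", "layer": None, "setting": row["setting"],
            "count": int(row["at_risk"]), "total": int(row["n"]),
            "share": row["pct_at_risk"] / 100.0,
        })
    for (setting, layer), c in sorted(report.setting_censuses.items()):
        rows.append({
            "quantity": "transitive_triads", "layer": layer, "setting": setting,
            "count": c.transitive_total, "total": c.total,
            "share": c.transitive_share,
        })
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """report.json, censuses.csv, correlations.csv, risk_table.csv, networks/."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    (root / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True, default=float) + "\n"
    )
    censuses_frame(report).to_csv(root / "censuses.csv", index=False)
    report.correlations.to_csv(root / "correlations.csv", index=False)
    risk = pd.concat(
        [report.risk_overall.assign(by="overall"),
         report.risk_by_gender.assign(by="gender"),
         report.risk_by_setting.assign(by="setting")],
        ignore_index=True,
    )
    risk.to_csv(root / "risk_table.csv", index=False)
    net_dir = root / "networks"
    net_dir.mkdir(exist_ok=True)
    for r in report.classrooms:
        for layer, net in r.layers.items():
            write_network(net, net_dir / f"{r.classroom}_{layer}.dl", dialect="ucinet_dl")
            write_network(net, net_dir / f"{r.classroom}_{layer}.edges", dialect="edge_list")
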