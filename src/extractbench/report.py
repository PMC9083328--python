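"""One-shot pipeline runner: validate → detect → compare → cv → overlap.

``run_all`` executes every analysis stage on one measurement file and
writes a deterministic directory of CSV tables, a machine-readable JSON
summary, the resolved configuration and a MANIFEST recording which stages
completed.  CSV tables are the contract; figures are optional artifacts and
any figure-rendering failure downgrades to a warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .detectability import DetectionRule, compute_detectability, coverage_counts, status_proportions
from .io import read_measurements
from .model import ConfigError, ExtractBenchError, MatrixKey, validate
from .overlap import shared_unique_lists, venn_overlap
from .protocol_stats import ComparisonConfig, compare_protocols, count_optimal_by_class
from .variability import band_summary, cv_records, median_mad_of_cv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(ExtractBenchError):
    """A pipeline stage failed; partial outputs were retained."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; serializable to YAML/JSON."""

    input: str
    outdir: str
    dialect: str = "long_csv"
    rule_numerator: int = 2
    rule_denominator: int = 3
    alpha: float = 0.05
    impute_fraction: float = 0.2
    denominator: int = 630
    cv_boundaries: tuple[float, float, float] = (10.0, 20.0, 30.0)
    overlap_protocol: str | None = None
    figures: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def detection_rule(self) -> DetectionRule:
        return DetectionRule(self.rule_numerator, self.rule_denominator)

    def comparison_config(self) -> ComparisonConfig:
        return ComparisonConfig(alpha=self.alpha, impute_fraction=self.impute_fraction)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cv_boundaries"] = list(self.cv_boundaries)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "cv_boundaries" in data:
            data["cv_boundaries"] = tuple(data["cv_boundaries"])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )


def _matrix_label(m: MatrixKey) -> str:
    return f"{m[0]}/{m[1]}"


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, index=index, float_format="%.12g")


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Raises :class:`PipelineError` after writing a MANIFEST if any stage
    fails; outputs of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_file(outdir / "resolved_config.yaml")

    manifest: dict[str, str] = {}
    summary: dict = {}
    failure: str | None = None

    def stage(name: str):
        def deco(fn):
            nonlocal failure
            if failure is not None:
                manifest[name] = "skipped"
                return None
            try:
                out = fn()
                manifest[name] = "ok"
                return out
            except Exception as exc:  # noqa: BLE001 - manifest must record any failure
                logger.error("stage %s failed: %s", name, exc)
                manifest[name] = f"failed: {exc}"
                failure = f"{name}: {exc}"
                return None
        return deco

    @stage("read")
    def table():
        return read_measurements(config.input, config.dialect)

    @stage("validate")
    def violations():
        v = validate(table)
        (outdir / "validation.txt").write_text(
            "\n".join(v) + ("\n" if v else ""), encoding="utf-8"
        )
        summary["n_validation_violations"] = len(v)
        return v

    @stage("detect")
    def det():
        d = compute_detectability(table, config.detection_rule())
        rows = []
        for matrix, dm in d.items():
            for prot in dm.detectable.columns:
                for met in dm.detectable.index:
                    rows.append(
                        {
                            "organism": matrix[0],
                            "tissue": matrix[1],
                            "protocol": prot,
                            "metabolite": met,
                            "detectable": bool(dm.detectable.loc[met, prot]),
                            "n_above_lod": int(dm.n_above_lod.loc[met, prot]),
                            "n_total": int(dm.n_total.loc[met, prot]),
                        }
                    )
        _write_csv(pd.DataFrame(rows), outdir / "detectability.csv", index=False)
        cov = pd.concat(
            {_matrix_label(m): coverage_counts(dm, table.panel) for m, dm in d.items()},
            names=["matrix", "protocol"],
        )
        _write_csv(cov, outdir / "coverage_counts.csv")
        summary["detectable_per_matrix"] = {
            _matrix_label(m): int(dm.detectable.any(axis=1).sum())
            for m, dm in d.items()
        }
        _write_csv(status_proportions(table), outdir / "status_proportions.csv")
        return d

    @stage("compare")
    def comparisons():
        comps = compare_protocols(
            table, config.comparison_config(), detectability=det
        )
        rows = []
        counts = {}
        for matrix, per_met in comps.items():
            for met, comp in per_met.items():
                top = comp.protocol_medians.idxmax()
                for prot in comp.protocol_medians.index:
                    rows.append(
                        {
                            "organism": matrix[0],
                            "tissue": matrix[1],
                            "metabolite": met,
                            "class": table.panel.class_of()[met],
                            "protocol": prot,
                            "median_log2": comp.protocol_medians[prot],
                            "in_optimal_set": prot in comp.optimal_set,
                            "unique_best": comp.unique_best == prot,
                            "anova_p": comp.anova_p,
                            "adj_p_vs_top": float(comp.tukey_adj_p.loc[prot, top]),
                        }
                    )
            counts[_matrix_label(matrix)] = count_optimal_by_class(
                per_met, table.panel, det[matrix]
            )
        _write_csv(pd.DataFrame(rows), outdir / "comparison.csv", index=False)
        optimal = pd.concat(
            {m: c.optimal for m, c in counts.items()}, names=["matrix", "protocol"]
        )
        unique = pd.concat(
            {m: c.unique_best for m, c in counts.items()}, names=["matrix", "protocol"]
        )
        _write_csv(optimal, outdir / "optimal_counts.csv")
        _write_csv(unique, outdir / "unique_best_counts.csv")
        summary["optimal_total_per_matrix_protocol"] = {
            m: {p: int(v) for p, v in c.optimal["total"].items()}
            for m, c in counts.items()
        }
        return comps

    @stage("cv")
    def cv():
        recs = cv_records(table, det, boundaries=config.cv_boundaries)
        frame = pd.DataFrame(
            [
                {
                    "organism": r.matrix_key[0],
                    "tissue": r.matrix_key[1],
                    "protocol": r.protocol,
                    "metabolite": r.metabolite,
                    "cv_percent": r.cv_percent,
                    "mad": r.mad,
                    "band": r.band.value,
                }
                for r in recs
            ]
        )
        _write_csv(frame, outdir / "cv.csv", index=False)
        summaries = []
        for matrix in det:
            for prot in det[matrix].detectable.columns:
                group = [
                    r for r in recs
                    if r.matrix_key == matrix and r.protocol == prot
                ]
                s = band_summary(
                    group, config.denominator, matrix_key=matrix, protocol=prot
                )
                summaries.append(s.as_row())
        _write_csv(pd.DataFrame(summaries), outdir / "band_summary.csv", index=False)
        _write_csv(median_mad_of_cv(recs), outdir / "cv_median_mad.csv")
        return recs

    @stage("overlap")
    def venn():
        if len(det) < 2:
            logger.info("single matrix: overlap stage skipped")
            return None
        protocols = sorted(
            {p for dm in det.values() for p in dm.detectable.columns}
        )
        prot = config.overlap_protocol
        if prot is None:
            prot = "75EtOH/MTBE" if "75EtOH/MTBE" in protocols else protocols[0]
        result = venn_overlap(det, prot)
        if result.regions is None:
            rows = [
                {
                    "protocol": prot,
                    "pattern": f"{_matrix_label(a)} & {_matrix_label(b)}",
                    "n_matrices": 2,
                    "count": n,
                }
                for (a, b), n in sorted(result.pairwise.items())
            ]
            _write_csv(pd.DataFrame(rows), outdir / "overlap.csv", index=False)
            summary["overlap_protocol"] = prot
            return result
        rows = [
            {
                "protocol": prot,
                "pattern": " & ".join(_matrix_label(m) for m in pattern),
                "n_matrices": len(pattern),
                "count": len(mets),
            }
            for pattern, mets in sorted(result.regions.items())
        ]
        _write_csv(pd.DataFrame(rows), outdir / "overlap.csv", index=False)
        _write_csv(
            shared_unique_lists(result), outdir / "shared_unique.csv", index=False
        )
        summary["overlap_protocol"] = prot
        summary["core_overlap"] = len(result.core())
        summary["overlap_union"] = result.union_size()
        return result

    if config.figures and failure is None:
        try:
            from . import figures

            figdir = outdir / "figures"
            figdir.mkdir(exist_ok=True)
            figures.render_all(table, det, cv, figdir)
            manifest["figures"] = "ok"
        except Exception as exc:  # noqa: BLE001 - figures never fail the run
            warnings.warn(f"figure rendering failed: {exc}")
            manifest["figures"] = f"warning: {exc}"

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if failure is not None:
        raise PipelineError(failure)
    return outdir
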