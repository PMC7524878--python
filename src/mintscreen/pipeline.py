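"""End-to-end orchestration of the screening pipeline.

Runs authentication, chemistry, germination scoring, bioactivity ranking,
dose-response fitting, and cytotoxicity analysis on a study directory
(real or synthetic) and collects everything into one report. Optional
inputs (e.g. the AO/EB nucleus table) mark their section "skipped" instead
of failing the run. Reports are deterministic: given the same bundle and
seeds, the JSON serialization is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import barcoding, bioactivity, chemistry, cytotoxicity, germination
from .synthetic_data import TUBULIN_LINE, WT

logger = logging.getLogger("mintscreen")


class StageError(RuntimeError):
    def __init__(self, stage: str, path, original: Exception):
        self.stage = stage
        self.path = path
        super().__init__(f"stage {stage!r} failed on {path}: {original}")


@dataclass
class StudyBundle:
    """Paths and run options for one screening study."""

    sequences: Path | None = None
    labels: Path | None = None
    peaks_dir: Path | None = None
    germination: Path | None = None
    mortality: Path | None = None
    nuclei: Path | None = None
    outgroup: str | None = None
    oil_dose: float = 0.1
    active_compound: str = "menthone/isomenthone"
    exclude_compounds: tuple[str, ...] = ("citral",)
    pooling: dict[str, str] | None = None  # None -> default isomer pooling
    thresholds: tuple[float, float] = cytotoxicity.DEFAULT_THRESHOLDS
    min_support: float = barcoding.DEFAULT_MIN_SUPPORT
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    distance_model: str = "p-distance"
    compare_lines: tuple[str, str] = (WT, TUBULIN_LINE)

    @classmethod
    def from_directory(cls, study_dir, **options) -> "StudyBundle":
        """Bundle the conventional file layout of a study directory."""
        d = Path(study_dir)

        def maybe(p: Path) -> Path | None:
            return p if p.exists() else None

        return cls(
            sequences=maybe(d / "sequences.fasta"),
            labels=maybe(d / "labels.csv"),
            peaks_dir=maybe(d / "peaks"),
            germination=maybe(d / "germination.csv"),
            mortality=maybe(d / "mortality.csv"),
            nuclei=maybe(d / "nuclei.csv"),
            **options,
        )


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:12]


def _stage(name: str, path):
    """Context for one pipeline stage: structured log line, error wrapping."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, path, exc) from exc
            digest = ""
            if path is not None and Path(str(path)).is_file():
                digest = _hash_file(path)
            logger.info(
                "stage=%s input=%s sha256=%s elapsed=%.3fs",
                name, path, digest, time.perf_counter() - self.t0,
            )
            return False

    return _Ctx()


def run_screen(bundle: StudyBundle) -> dict:
    """Execute every stage the bundle's inputs allow; return the report.

    Stages with a missing required input short-circuit with a clear message
    in the report; the AO/EB section is optional and marked "skipped" when
    absent.
    """
    report: dict = {"seeds": {"bootstrap": bundle.rng_seed}}

    # -- authentication ----------------------------------------------------
    if bundle.sequences is None or bundle.labels is None:
        report["authentication"] = {"status": "skipped: sequences or labels missing"}
    else:
        with _stage("authenticate", bundle.sequences):
            labels = dict(
                pd.read_csv(bundle.labels)[["accession", "declared_taxon"]]
                .itertuples(index=False)
            )
            aln = barcoding.read_fasta_alignment(bundle.sequences, labels)
            tree = barcoding.bootstrap_support(
                aln,
                n_reps=bundle.bootstrap_reps,
                rng_seed=bundle.rng_seed,
                model=bundle.distance_model,
                outgroup=bundle.outgroup,
            )
            reports = barcoding.flag_mislabels(
                tree, labels, bundle.min_support, outgroup=bundle.outgroup
            )
            report["authentication"] = {
                "status": "ok",
                "newick": tree.to_newick(),
                "flagged": [
                    {"accession": r.accession, "declared": r.declared,
                     "inferred": r.inferred, "support": r.clade_support}
                    for r in reports if r.status == "flagged"
                ],
                "unresolved": [r.accession for r in reports
                               if r.status == "unresolved"],
                "untestable": [r.accession for r in reports
                               if r.status == "untestable"],
                "confirmed": [r.accession for r in reports if r.status == "ok"],
            }

    # -- chemistry ---------------------------------------------------------
    matrix = None
    if bundle.peaks_dir is None:
        report["chemistry"] = {"status": "skipped: peak tables missing"}
    else:
        with _stage("chem", bundle.peaks_dir):
            tables = [
                chemistry.pool_isomers(
                    chemistry.load_peak_table(p), bundle.pooling
                )
                for p in sorted(Path(bundle.peaks_dir).glob("*.csv"))
            ]
            matrix = chemistry.build_abundance_matrix(tables)
            report["chemistry"] = {
                "status": "ok",
                "accessions": matrix.accessions,
                "compounds": matrix.compounds,
            }

    # -- germination -------------------------------------------------------
    inhibition = None
    if bundle.germination is None:
        report["germination"] = {"status": "skipped: germination counts missing"}
    else:
        with _stage("germination", bundle.germination):
            counts = pd.read_csv(bundle.germination)
            inhibition = germination.inhibition_table(counts)
            report["germination"] = {
                "status": "ok",
                "inhibition": [
                    {"treatment": t, "dose": d, "inhibition": round(i, 6),
                     "se": round(s, 6)}
                    for t, d, i, s in inhibition.itertuples(index=False)
                ],
            }

    # -- bioactivity score -------------------------------------------------
    if matrix is None or inhibition is None:
        report["bioactivity"] = {
            "status": "skipped: needs both peak tables and germination counts"
        }
    else:
        with _stage("score", bundle.germination):
            oil = inhibition[
                inhibition["treatment"].str.startswith("oil:")
                & (inhibition["dose"] == bundle.oil_dose)
            ]
            g = {
                t.removeprefix("oil:"): i
                for t, i in zip(oil["treatment"], oil["inhibition"])
            }
            bt = bioactivity.bioactivity_score(matrix, g)
            ranking = bioactivity.rank_candidates(
                bt, set(bundle.exclude_compounds)
            )
            heat = bioactivity.heatmap_matrix(matrix, bt)
            report["bioactivity"] = {
                "status": "ok",
                "scores": {c: round(v, 6) for c, v in bt.scores.items()},
                "candidates": list(ranking.candidates.index),
                "excluded": list(ranking.excluded.index),
                "heatmap_rows": list(heat.index),
            }

    # -- germination dose-response fits -------------------------------------
    if inhibition is None:
        report["dose_response"] = {"status": "skipped: germination counts missing"}
    else:
        with _stage("doseresponse", bundle.germination):
            fits = {}
            compounds = inhibition[
                ~inhibition["treatment"].str.startswith(("oil:", "control:"))
            ]
            for treatment, sub in compounds.groupby("treatment"):
                if sub["dose"].nunique() < 2:
                    continue
                # unweighted: few-replicate empirical SEs make poor weights
                fit = germination.fit_dose_response(
                    sub["dose"].to_numpy(),
                    sub["inhibition"].to_numpy(),
                )
                fits[treatment] = {
                    "model": fit.model,
                    "lower": round(fit.lower, 4),
                    "upper": round(fit.upper, 4),
                    "ec50": round(fit.ec50, 6),
                    "slope": round(fit.slope, 4),
                    "converged": fit.converged,
                }
            report["dose_response"] = {"status": "ok", "fits": fits}

    # -- cytotoxicity --------------------------------------------------------
    if bundle.mortality is None:
        report["cytotoxicity"] = {"status": "skipped: mortality counts missing"}
    else:
        with _stage("cytotox", bundle.mortality):
            records = pd.read_csv(bundle.mortality)
            table = cytotoxicity.mortality_table(records)
            section: dict = {
                "status": "ok",
                "mortality": [
                    {"compound": c, "line": l, "dose": d, "time": t,
                     "mortality": round(m, 4), "se": round(s, 4)}
                    for c, l, d, t, m, s, _n in table.itertuples(index=False)
                ],
            }
            line_a, line_b = bundle.compare_lines
            series = {
                line: table[
                    (table["compound"] == bundle.active_compound)
                    & (table["line"] == line)
                    & (table["time"] == 15.0)
                ]
                for line in (line_a, line_b)
            }
            if all(len(s) >= 4 for s in series.values()):
                ls = cytotoxicity.line_sensitivity(
                    series[line_a], series[line_b]
                )
                section["line_sensitivity"] = {
                    "compound": bundle.active_compound,
                    "lines": [line_a, line_b],
                    "ec50_fold": round(ls.fold.ratio, 4),
                    "ec50": {
                        line_a: round(ls.fit_a.ec50, 6),
                        line_b: round(ls.fit_b.ec50, 6),
                    },
                }
            report["cytotoxicity"] = section

    # -- AO/EB (optional) -----------------------------------------------------
    if bundle.nuclei is None:
        report["aoeb"] = {"status": "skipped: nuclei table missing"}
    else:
        with _stage("aoeb", bundle.nuclei):
            nuclei = pd.read_csv(bundle.nuclei)
            dists = cytotoxicity.class_frequency_distribution(
                nuclei, bundle.thresholds
            )
            report["aoeb"] = {
                "status": "ok",
                "distributions": [
                    {"compound": d.compound, "dose": d.dose,
                     "frequencies": {k: round(v, 6)
                                     for k, v in d.frequencies.items()},
                     "n": d.total, "unclassifiable": d.unclassifiable}
                    for d in dists
                ],
            }

    return report


def write_report(report: dict, out_prefix, formats=("json", "text")) -> list[Path]:
    """Serialize a report as JSON and/or a human-readable text summary."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        p = out_prefix.with_suffix(".json")
        p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(p)
    if "text" in formats:
        p = out_prefix.with_suffix(".txt")
        p.write_text(render_text_report(report))
        written.append(p)
    return written


def render_text_report(report: dict) -> str:
    lines = ["mintscreen report", "=" * 17, ""]
    auth = report.get("authentication", {})
    lines.append(f"Authentication: {auth.get('status', 'absent')}")
    for f in auth.get("flagged", []):
        lines.append(
            f"  flagged {f['accession']}: declared {f['declared']}, "
            f"placed with {f['inferred']} (support {f['support']:.0f}%)"
        )
    for acc in auth.get("unresolved", []):
        lines.append(f"  unresolved {acc}")
    bio = report.get("bioactivity", {})
    lines.append("")
    lines.append(f"Bioactivity: {bio.get('status', 'absent')}")
    candidates = bio.get("candidates", [])
    if bio.get("status") == "ok" and not candidates:
        lines.append("  no candidates")
    for rank, compound in enumerate(candidates, start=1):
        lines.append(f"  {rank}. {compound}  B={bio['scores'][compound]:.1f}")
    if bio.get("excluded"):
        lines.append(f"  excluded (positive controls): {', '.join(bio['excluded'])}")
    dr = report.get("dose_response", {})
    lines.append("")
    lines.append(f"Dose-response: {dr.get('status', 'absent')}")
    for treatment, fit in sorted(dr.get("fits", {}).items()):
        lines.append(
            f"  {treatment}: EC50={fit['ec50']:.4g} ({fit['model']}), "
            f"slope={fit['slope']:.3g}, converged={fit['converged']}"
        )
    cyto = report.get("cytotoxicity", {})
    lines.append("")
    lines.append(f"Cytotoxicity: {cyto.get('status', 'absent')}")
    ls = cyto.get("line_sensitivity")
    if ls:
        lines.append(
            f"  {ls['compound']}: EC50 fold {ls['lines'][0]}/{ls['lines'][1]} "
            f"= {ls['ec50_fold']:.3g}"
        )
    lines.append("")
    lines.append(f"AO/EB: {report.get('aoeb', {}).get('status', 'absent')}")
    return "\n".join(lines) + "\n"
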