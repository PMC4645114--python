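"""Campaign orchestration: QC -> features -> train -> rank -> filter ->
cluster -> report.

Every stage logs its input/output counts so funnel audits are diff-able;
the report is a plain JSON-serializable dict and is byte-identical for
identical config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ensemblevs import chemio, chemfilters, fusion, screen_eval, structure_qc
from ensemblevs.chemio import FixtureBundle, FixtureSpec, MoleculeRecord, ScoreTable

logger = logging.getLogger(__name__)


@dataclass
class CampaignConfig:
    """All thresholds and inputs of one screening campaign."""

    seed: int = 0
    rmsd_max: float = 2.0
    p_max: float = 1e-20
    top_n: int = 100
    cluster_threshold: float = 0.85
    decoy_ratio: int = 20
    n_bins: int = 10
    max_confs: int = 100
    fixture: FixtureSpec | None = None
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rmsd_max", "p_max", "top_n", "cluster_threshold", "decoy_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fixture is None and not self.paths:
            raise ValueError("config needs either a fixture section or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        fixture = doc.pop("fixture", None)
        if fixture is not None:
            fixture = FixtureSpec(**fixture)
        return cls(fixture=fixture, **doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


def _load_inputs(config: CampaignConfig) -> FixtureBundle:
    if config.fixture is not None:
        spec = dataclasses.replace(config.fixture, seed=config.seed)
        return chemio.generate_fixtures(spec)
    paths = config.paths
    molecules = chemio.read_library(paths["library"])
    active_ids = set(Path(paths["actives"]).read_text().split())
    for rec in molecules:
        rec.label = "active" if rec.id in active_ids else "decoy"
    score_tables = [
        chemio.read_score_table(p) for p in sorted(Path(paths["scores_dir"]).glob("*.csv"))
    ]
    fit_tables = []
    if paths.get("fits_dir"):
        for p in sorted(Path(paths["fits_dir"]).glob("*.csv")):
            table = chemio.read_score_table(p)
            table.score_mode = "fit"
            fit_tables.append(table)
    redock: dict[str, float] = {}
    with Path(paths["rmsd"]).open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("structure_id"):
                continue
            sid, rmsd = line.split(",")[:2]
            redock[sid] = float(rmsd)
    return FixtureBundle(
        molecules=molecules,
        score_tables=score_tables,
        fit_tables=fit_tables,
        redock_rmsd=redock,
    )


def _qc_stage(config: CampaignConfig, bundle: FixtureBundle) -> list[structure_qc.StructureQCResult]:
    active_ids = {m.id for m in bundle.molecules if m.label == "active"}
    results = []
    for table in bundle.score_tables:
        act = [s for mid, s in table.entries.items() if mid in active_ids]
        dec = [s for mid, s in table.entries.items() if mid not in active_ids]
        log10_p = structure_qc.discrimination_log10p(act, dec)
        results.append(
            structure_qc.StructureQCResult(
                structure_id=table.structure_id,
                redock_rmsd=bundle.redock_rmsd.get(table.structure_id, 0.0),
                log10_p=log10_p,
            )
        )
    structure_qc.qualify_structures(results, config.rmsd_max, config.p_max)
    return results


def run_campaign(config: CampaignConfig) -> dict:
    """Execute the full screening funnel and return the campaign report."""
    bundle = _load_inputs(config)
    molecules = bundle.molecules
    counts = {"library": len(molecules)}
    logger.info("stage load: %d molecules, %d structures", len(molecules), len(bundle.score_tables))

    qc_results = _qc_stage(config, bundle)
    qualified = [r for r in qc_results if r.qualified]
    if not qualified:
        raise RuntimeError("stage qc: no structure qualified")
    qualified_ids = {r.structure_id for r in qualified}
    counts["structures_total"] = len(qc_results)
    counts["structures_qualified"] = len(qualified)
    logger.info("stage qc: %d/%d structures qualified", len(qualified), len(qc_results))

    actives = [m for m in molecules if m.label == "active"]
    decoy_pool = [m for m in molecules if m.label == "decoy"]
    training = fusion.build_training_set(
        actives, decoy_pool, ratio=config.decoy_ratio, seed=config.seed
    )
    counts["training_actives"] = sum(1 for m in training if m.label == "active")
    counts["training_decoys"] = sum(1 for m in training if m.label == "decoy")
    logger.info(
        "stage training-set: %d actives + %d decoys",
        counts["training_actives"],
        counts["training_decoys"],
    )

    score_tables = [t for t in bundle.score_tables if t.structure_id in qualified_ids]
    fit_tables = [t for t in bundle.fit_tables if t.structure_id in qualified_ids]
    train_matrix = fusion.assemble_features(training, score_tables, fit_tables)
    # docking orientation: more negative = better; flip so larger = better
    train_matrix.values[:, [c.startswith("dock:") for c in train_matrix.channels]] *= -1.0
    bins = fusion.fit_bins(train_matrix, config.n_bins)
    model = fusion.train_nbc(train_matrix, bins)
    scores = fusion.score_matrix(model, train_matrix)
    report_eval = screen_eval.confusion_metrics(scores, train_matrix.labels, threshold=0.0)
    logger.info("stage train: AUC %.3f on the training set", report_eval.auc)

    library_matrix = fusion.assemble_features(molecules, score_tables, fit_tables, labeled=False)
    library_matrix.values[:, [c.startswith("dock:") for c in library_matrix.channels]] *= -1.0
    hits = fusion.rank_library(model, library_matrix, top_n=config.top_n)
    counts["ranked"] = len(hits)
    logger.info("stage rank: top %d of %d", len(hits), len(molecules))

    by_id = {m.id: m for m in molecules}
    have_structures = all(by_id[h.molecule_id].mol is not None for h in hits)
    passing = []
    if have_structures:
        for hit in hits:
            rec = by_id[hit.molecule_id]
            props = chemfilters.compute_properties(rec)
            ro5 = chemfilters.lipinski_ro5(props, molecule_id=rec.id)
            reos = chemfilters.reos_filter(rec, props)
            hit.passed_filters = ro5.passed and reos.passed
            hit.filter_violations = ro5.violations + reos.violations
            if hit.passed_filters:
                passing.append(hit)
    else:
        logger.warning("stage filter: library has no structures; filters skipped")
        for hit in hits:
            hit.passed_filters = True
        passing = list(hits)
    counts["filtered"] = len(passing)
    logger.info("stage filter: %d/%d hits pass Ro5+REOS", len(passing), len(hits))

    if passing and have_structures:
        fps = [chemfilters.fingerprint(by_id[h.molecule_id], "maccs") for h in passing]
        labels = chemfilters.cluster_by_similarity(fps, config.cluster_threshold)
        seen: set[int] = set()
        for hit, cluster in zip(passing, labels):
            hit.cluster = cluster
            hit.representative = cluster not in seen  # hits arrive rank-ordered
            seen.add(cluster)
        representatives = [h for h in passing if h.representative]
    else:
        # no structures => no similarity information; every hit is a singleton
        for i, hit in enumerate(passing):
            hit.cluster = i
            hit.representative = True
        representatives = list(passing)
    counts["clusters"] = len({h.cluster for h in passing}) if passing else 0
    counts["representatives"] = len(representatives)
    logger.info(
        "stage cluster: %d clusters, %d representatives", counts["clusters"], counts["representatives"]
    )

    report = {
        "config": {
            "seed": config.seed,
            "rmsd_max": config.rmsd_max,
            "p_max": config.p_max,
            "top_n": config.top_n,
            "cluster_threshold": config.cluster_threshold,
            "decoy_ratio": config.decoy_ratio,
            "n_bins": config.n_bins,
        },
        "counts": counts,
        "structures": [
            {
                "structure_id": r.structure_id,
                "redock_rmsd": round(r.redock_rmsd, 6),
                "log10_p": round(r.log10_p, 6),
                "qualified": r.qualified,
            }
            for r in qc_results
        ],
        "metrics": {k: round(v, 6) for k, v in report_eval.to_dict().items()},
        "hits": [
            {
                "rank": h.rank,
                "molecule_id": h.molecule_id,
                "score": round(h.score, 6),
                "passed_filters": h.passed_filters,
                "cluster": h.cluster,
                "representative": bool(h.representative),
            }
            for h in passing
        ],
        "candidates": [h.molecule_id for h in representatives],
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
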