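"""End-to-end orchestration from a single YAML config.

Stages run in dependency order (simulate -> chromstate -> programs; synergy
and rime are independent), communicate only through files, and are recorded
in a machine-readable run report with a checksum manifest, so a run is
reproducible and each stage independently re-runnable.
"""

from __future__ import annotations

import hashlib
import logging
import traceback
from pathlib import Path

import pandas as pd
import yaml

from plastichrom import __version__, chromstate, programs, rime, synergy, synthio
from plastichrom import io as pio
from plastichrom.config import ConfigError, SimConfig

logger = logging.getLogger(__name__)

# programs runs before chromstate so its DE table can feed the
# transition-class enrichment; synergy and rime are independent
STAGES = ("simulate", "programs", "chromstate", "synergy", "rime")
_DEPENDENTS = {"simulate": ("programs", "chromstate")}


class RunConfig:
    """Validated pipeline configuration (see docs for the YAML schema)."""

    def __init__(self, raw: dict, base_dir: Path | None = None):
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        unknown = set(raw) - set(STAGES) - {"seed", "outdir"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        self.base_dir = Path(base_dir or ".")
        self.seed = int(raw.get("seed", 0))
        outdir = raw.get("outdir")
        if outdir is None:
            raise ConfigError("config must set 'outdir'")
        self.outdir = self._resolve(outdir)
        self.stages = {s: dict(raw.get(s) or {}) for s in STAGES}
        for s in STAGES:
            self.stages[s].setdefault("enabled", False)

    def _resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def enabled(self, stage: str) -> bool:
        return bool(self.stages[stage].get("enabled"))

    def path(self, stage: str, key: str, default: Path | None = None) -> Path | None:
        val = self.stages[stage].get(key)
        if val is None:
            return default
        return self._resolve(val)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        return cls(yaml.safe_load(path.read_text()) or {}, base_dir=path.parent)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> dict:
    """Check file existence, format shape and id cross-references.

    Always returns a report dict with ``errors`` and ``warnings`` lists;
    never raises on bad inputs.
    """
    errors: list[str] = []
    warnings: list[str] = []
    sim_dir = config.outdir / "sim"

    def need(stage: str, key: str, default: Path | None = None) -> Path | None:
        p = config.path(stage, key, default)
        if p is None:
            errors.append(f"{stage}: no path configured for '{key}'")
            return None
        if not p.exists():
            # simulate outputs may not exist yet; only an error if simulate is off
            if config.enabled("simulate") and default is not None and p == default:
                return None
            errors.append(f"{stage}: input file not found: {p}")
            return None
        return p

    promoter_genes: set[str] = set()
    expr_genes: set[str] = set()

    if config.enabled("chromstate"):
        p = need("chromstate", "promoters", sim_dir / "promoters.tsv")
        if p:
            try:
                promoter_genes = set(pio.read_promoters(p)["gene_id"])
            except (pio.ParseError, KeyError) as exc:
                errors.append(str(exc))
        for mark in synthio.MARKS:
            for cond in synthio.CONDITIONS:
                bp = need("chromstate", f"peaks_{mark}_{cond}",
                          sim_dir / f"peaks_{mark}_{cond}.bed")
                if bp:
                    try:
                        pio.read_bed(bp)
                    except pio.ParseError as exc:
                        errors.append(str(exc))

    if config.enabled("programs"):
        cdir = need("programs", "counts_dir", sim_dir)
        if cdir:
            try:
                expr_genes = set(pio.read_counts_mtx(cdir).columns)
            except Exception as exc:  # noqa: BLE001 - report, don't raise
                errors.append(f"programs: unreadable count matrix in {cdir}: {exc}")
        gmt = need("programs", "gene_sets", sim_dir / "programs.gmt")
        if gmt:
            try:
                sets = pio.read_gmt(gmt)
                if not sets:
                    errors.append(f"programs: empty GMT file {gmt}")
            except pio.ParseError as exc:
                errors.append(str(exc))
        need("programs", "cellmeta", sim_dir / "cellmeta.tsv")

    if promoter_genes and expr_genes:
        overlap = len(promoter_genes & expr_genes)
        if overlap == 0:
            warnings.append("promoter gene ids disjoint from expression gene ids (overlap 0)")

    if config.enabled("synergy"):
        plates = config.stages["synergy"].get("plates") or [sim_dir / "plate_drugA_drugB.csv"]
        for plate in plates:
            p = config._resolve(plate)
            if not p.exists():
                if not config.enabled("simulate"):
                    errors.append(f"synergy: plate file not found: {p}")
            else:
                try:
                    pio.read_plate_csv(p)
                except pio.ParseError as exc:
                    errors.append(str(exc))

    if config.enabled("rime"):
        p = need("rime", "counts", sim_dir / "spectral_counts.tsv")
        if p:
            try:
                pio.read_spectral_counts(p)
            except pio.ParseError as exc:
                errors.append(str(exc))

    return {"errors": errors, "warnings": warnings, "n_errors": len(errors)}


# ---------------------------------------------------------------------------
# stage runners

def _run_simulate(config: RunConfig) -> dict:
    params = dict(config.stages["simulate"].get("config") or {})
    params.setdefault("seed", config.seed)
    cfg = SimConfig.from_dict(params)
    manifest = synthio.simulate_to_dir(cfg, config.outdir / "sim",
                                       peak_window=int(config.stages["simulate"].get("peak_window", 1000)))
    return {"params": cfg.to_dict(), "outputs": manifest}


def _run_chromstate(config: RunConfig) -> dict:
    st = config.stages["chromstate"]
    sim_dir = config.outdir / "sim"
    window = int(st.get("window", chromstate.DEFAULT_WINDOW))
    promoters = pio.read_promoters(config.path("chromstate", "promoters", sim_dir / "promoters.tsv"))
    peaks = {}
    for mark in synthio.MARKS:
        for cond in synthio.CONDITIONS:
            path = config.path("chromstate", f"peaks_{mark}_{cond}",
                               sim_dir / f"peaks_{mark}_{cond}.bed")
            peaks[(mark, cond)] = pio.read_bed(path)
    presence = chromstate.assign_mark_presence(peaks, promoters, window=window)
    states = chromstate.call_states(presence)
    outdir = config.outdir / "chromstate"
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_tsv(states, outdir / "states.tsv", {"window": window, "seed": config.seed})

    by_cond = {c: g.drop(columns="condition") for c, g in states.groupby("condition")}
    transitions = chromstate.transition_matrix(by_cond["cond1"], by_cond["cond2"])
    pio.write_tsv(transitions.to_long(), outdir / "transitions.tsv", {"seed": config.seed})

    headline = {"transition_matrix": transitions.counts.to_dict(),
                "n_genes": transitions.total}
    de_path = config.path("chromstate", "de", (config.outdir / "programs" / "de.tsv"))
    if de_path is not None and de_path.exists():
        de = pio.read_tsv(de_path)
        enr = chromstate.integrate_with_de(
            transitions, de,
            direction=st.get("direction", "up"),
            q_max=float(st.get("q_max", 0.05)),
        )
        pio.write_tsv(enr, outdir / "enrichment.tsv", {"seed": config.seed})
        top = enr[enr["class_type"] == "cond2_state"].iloc[0]
        headline["top_cond2_state"] = {"class": top["class"], "q": float(top["q"])}
    return {"params": {"window": window}, "outputs": {"dir": str(outdir)}, "headline": headline}


def _run_programs(config: RunConfig) -> dict:
    st = config.stages["programs"]
    sim_dir = config.outdir / "sim"
    counts = pio.read_counts_mtx(config.path("programs", "counts_dir", sim_dir))
    meta = pd.read_csv(config.path("programs", "cellmeta", sim_dir / "cellmeta.tsv"),
                       sep="\t").set_index("cell_id")
    gene_sets = pio.read_gmt(config.path("programs", "gene_sets", sim_dir / "programs.gmt"))
    norm = programs.normalize_log(counts)
    meta = meta.reindex(norm.index)
    outdir = config.outdir / "programs"
    outdir.mkdir(parents=True, exist_ok=True)

    scores = programs.score_signatures(norm, gene_sets)
    pio.write_tsv(scores, outdir / "scores.tsv", {"seed": config.seed}, index=True)
    headline: dict = {}
    if scores.shape[1] >= 2:
        subtype = programs.assign_subtype(scores, level="cluster", clusters=meta["cluster"])
        pio.write_tsv(subtype, outdir / "subtypes.tsv", {"seed": config.seed}, index=True)
        headline["subtype_counts"] = subtype["subtype"].value_counts().to_dict()

    if "pseudotime" in meta:
        profiles = []
        for name in scores.columns:
            prof = programs.pseudotime_profile(scores[name], meta["pseudotime"],
                                               df=int(st.get("spline_df", 5)))
            prof.insert(0, "set", name)
            profiles.append(prof)
        pio.write_tsv(pd.concat(profiles, ignore_index=True), outdir / "profiles.tsv",
                      {"seed": config.seed})

    group_a = meta.index[meta["treatment"] == "EZH2i"].tolist()
    group_b = meta.index[meta["treatment"] == "vehicle"].tolist()
    de = programs.de_rank(norm, group_a, group_b)
    pio.write_tsv(de, outdir / "de.tsv", {"contrast": "EZH2i_vs_vehicle", "seed": config.seed})

    ranking = de.set_index("gene_id")["rank_key"]
    gsea = programs.gsea_preranked(ranking, gene_sets,
                                   n_perm=int(st.get("n_perm", 1000)), seed=config.seed)
    pio.write_tsv(gsea.table, outdir / "gsea.tsv",
                  {"n_perm": gsea.n_permutations, "seed": config.seed})
    fdr = float(st.get("gsea_fdr", 0.25))
    sig = gsea.table[gsea.table["q"] < fdr]
    headline["gsea_top"] = gsea.table.head(3)[["set", "nes", "q"]].to_dict(orient="records")
    headline["gsea_n_significant"] = int(len(sig))
    return {"params": {"n_perm": gsea.n_permutations, "gsea_fdr": fdr},
            "outputs": {"dir": str(outdir)}, "headline": headline}


def _run_synergy(config: RunConfig) -> dict:
    sim_dir = config.outdir / "sim"
    plates = config.stages["synergy"].get("plates") or [sim_dir / "plate_drugA_drugB.csv"]
    outdir = config.outdir / "synergy"
    outdir.mkdir(parents=True, exist_ok=True)
    rows, surfaces = [], []
    for plate_path in plates:
        p = config._resolve(plate_path)
        doses_a, doses_b, raw = pio.read_plate_csv(p)
        summ = synergy.score_plate(doses_a, doses_b, raw)
        rows.append({"plate": p.name, "summary": summ.summary,
                     "replicate_sd": summ.replicate_sd, "n_wells": summ.n_wells})
        surf = summ.surface_frame()
        surf.insert(0, "plate", p.name)
        surfaces.append(surf)
    summary_df = pd.DataFrame(rows)
    pio.write_tsv(summary_df, outdir / "summary.tsv", {"seed": config.seed})
    pio.write_tsv(pd.concat(surfaces, ignore_index=True), outdir / "surface.tsv",
                  {"seed": config.seed})
    return {"params": {"n_plates": len(plates)},
            "outputs": {"dir": str(outdir)},
            "headline": {"summaries": rows}}


def _run_rime(config: RunConfig) -> dict:
    st = config.stages["rime"]
    sim_dir = config.outdir / "sim"
    table = pio.read_spectral_counts(config.path("rime", "counts", sim_dir / "spectral_counts.tsv"))
    mode = st.get("mode", "fdr")
    if mode == "fdr":
        hits = rime.nominate_fdr(table, q_max=float(st.get("q", 0.1)),
                                 min_detected=int(st.get("min_detected", 2)))
    elif mode == "venn":
        hits = rime.nominate_venn(table, min_count=int(st.get("min_count", 5)))
    else:
        raise ConfigError(f"unknown rime mode {mode!r}")
    outdir = config.outdir / "rime"
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_tsv(hits.reset_index(), outdir / "hits.tsv", {"mode": mode, "seed": config.seed})
    return {"params": {"mode": mode}, "outputs": {"dir": str(outdir)},
            "headline": {"n_hits": int(len(hits))}}


_RUNNERS = {
    "simulate": _run_simulate,
    "chromstate": _run_chromstate,
    "programs": _run_programs,
    "synergy": _run_synergy,
    "rime": _run_rime,
}


def run_all(config: RunConfig) -> dict:
    """Execute all enabled stages and write ``report.json`` in the outdir.

    Failure of a stage halts its dependents but not independent stages; the
    report's ``status`` is "success" only if nothing failed.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": f"plastichrom {__version__}",
        "seed": config.seed,
        "stages": {},
    }
    failed: set[str] = set()
    skipped: set[str] = set()
    for stage in STAGES:
        if not config.enabled(stage):
            report["stages"][stage] = {"status": "disabled"}
            continue
        blockers = [p for p, deps in _DEPENDENTS.items()
                    if stage in deps and config.enabled(p) and p in failed | skipped]
        if blockers:
            skipped.add(stage)
            report["stages"][stage] = {"status": "skipped", "blocked_by": blockers}
            continue
        try:
            result = _RUNNERS[stage](config)
            report["stages"][stage] = {"status": "success", **result}
        except Exception as exc:  # noqa: BLE001 - recorded in report
            logger.error("stage %s failed: %s", stage, exc)
            failed.add(stage)
            report["stages"][stage] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
    manifest = {}
    for path in sorted(config.outdir.rglob("*")):
        if path.is_file() and path.name != "report.json":
            manifest[str(path.relative_to(config.outdir))] = _sha256(path)
    report["manifest"] = manifest
    report["status"] = "failed" if failed else "success"
    pio.write_json(report, config.outdir / "report.json")
    return report
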