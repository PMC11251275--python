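"""File formats, configuration, and the pipeline driver.

Tables are UTF-8 CSV/TSV with headers and '.' decimals; sequences are
FASTA (wrapped at 60 columns); reports and the run manifest are JSON.
Readers validate rather than coerce: NaN absorbances, negative CABP or
non-monotone times are reported with their row numbers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from . import __version__
from .assay import ACTIVITY_THRESHOLD_KCAT, AssayConstants
from .selection import SequenceRecord
from .titration import KineticResult, TitrationSeries
from .traces import AbsorbanceTrace

TRACE_COLUMNS = ["sample_id", "cabp_nM", "dilution", "time_s", "a340"]


class ParseError(ValueError):
    """Input file failed validation; the message names the offending row."""


# ---------------------------------------------------------------------------
# traces


def write_traces_csv(series_list, path) -> None:
    """Write one or more titration series as long-format CSV.

    A ``replicate`` column distinguishes wells that share (sample_id,
    cabp_nM), e.g. the duplicate zero-CABP wells.
    """
    if isinstance(series_list, TitrationSeries):
        series_list = [series_list]
    frames = []
    for series in series_list:
        seen: dict = {}
        for tr in series.traces:
            key = (tr.sample_id, tr.cabp_nM)
            rep = seen.get(key, 0)
            seen[key] = rep + 1
            frames.append(pd.DataFrame({
                "sample_id": tr.sample_id,
                "cabp_nM": tr.cabp_nM,
                "dilution": tr.dilution,
                "replicate": rep,
                "time_s": tr.times,
                "a340": tr.a340,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list:
    """Read long-format traces into :class:`AbsorbanceTrace` objects.

    Rows are grouped by (sample_id, cabp_nM, replicate); without a
    ``replicate`` column, a new trace starts whenever time resets in file
    order.  Times are sorted canonically within each trace.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ["cabp_nM", "dilution", "time_s", "a340"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing {col!r} at data row "
                f"{int(bad[0]) + 2}")  # +2: header line and 1-based
        df[col] = vals
    if (df["cabp_nM"] < 0).any():
        row = int(df.index[df["cabp_nM"] < 0][0]) + 2
        raise ParseError(f"{path}: negative CABP concentration at row {row}")

    if "replicate" not in df.columns:
        # infer trace boundaries from time resets within each (sample, cabp)
        rep = np.zeros(len(df), dtype=int)
        counters: dict = {}
        last_time: dict = {}
        for i, (sid, c, t) in enumerate(
                zip(df["sample_id"], df["cabp_nM"], df["time_s"])):
            key = (sid, c)
            if key in last_time and t <= last_time[key]:
                counters[key] = counters.get(key, 0) + 1
            rep[i] = counters.get(key, 0)
            last_time[key] = t
        df = df.assign(replicate=rep)

    traces = []
    for (sid, cabp, rep), grp in df.groupby(
            ["sample_id", "cabp_nM", "replicate"], sort=False):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ParseError(
                f"{path}: duplicate time point in trace "
                f"({sid}, {cabp} nM, replicate {rep})")
        dil = grp["dilution"].to_numpy(dtype=float)
        if len(np.unique(dil)) != 1:
            raise ParseError(
                f"{path}: inconsistent dilution in trace ({sid}, {cabp} nM)")
        traces.append(AbsorbanceTrace(
            sample_id=str(sid), cabp_nM=float(cabp), dilution=float(dil[0]),
            times=times, a340=grp["a340"].to_numpy(dtype=float),
        ))
    return traces


def group_traces_into_series(
    traces, constants: AssayConstants,
    batch_ids: dict | None = None,
    reference_id: str | None = None,
) -> list:
    """Bundle traces into one :class:`TitrationSeries` per sample id."""
    by_sample: dict[str, list] = {}
    for tr in traces:
        by_sample.setdefault(tr.sample_id, []).append(tr)
    out = []
    for sid, trs in by_sample.items():
        out.append(TitrationSeries(
            sample_id=sid, traces=trs, constants=constants,
            dilution=trs[0].dilution,
            batch_id=(batch_ids or {}).get(sid),
            is_reference=(sid == reference_id),
        ))
    return out


# ---------------------------------------------------------------------------
# panels


PANEL_VOCAB = {
    "trophic_mode": {
        "photo": "photo", "phototroph": "photo", "phototrophy": "photo",
        "chemo": "chemo", "chemotroph": "chemo", "chemotrophy": "chemo",
    },
    "carboxysome": {
        "yes": "yes", "y": "yes", "true": "yes", "1": "yes",
        "no": "no", "n": "no", "false": "no", "0": "no",
    },
    "clade": {
        "alpha_cyano": "alpha_cyano", "alpha-cyano": "alpha_cyano",
        "alpha": "alpha_cyano",
        "beta_cyano": "beta_cyano", "beta-cyano": "beta_cyano",
        "beta": "beta_cyano",
        "ccm_proteo": "ccm_proteo", "ccm-proteo": "ccm_proteo",
        "proteo": "ccm_proteo",
        "other": "other",
    },
}

PANEL_REQUIRED = ["variant_id", "kcat"]
PANEL_LABELS = ["trophic_mode", "carboxysome", "clade"]


def _normalize_labels(df: pd.DataFrame, path) -> pd.DataFrame:
    for col, vocab in PANEL_VOCAB.items():
        if col not in df.columns:
            continue
        normed = []
        for i, raw in enumerate(df[col]):
            if pd.isna(raw):
                normed.append(np.nan)
                continue
            key = str(raw).strip().lower()
            if key not in vocab:
                raise ParseError(
                    f"{path}: unknown {col} label {raw!r} at data row {i + 2}")
            normed.append(vocab[key])
        df[col] = normed
    return df


def read_panel(
    path,
    column_map: dict | None = None,
    meta_path=None,
    meta_column_map: dict | None = None,
) -> pd.DataFrame:
    """Read a variant panel table (TSV/CSV by extension).

    ``column_map`` maps file column names to canonical names
    (variant_id, kcat, trophic_mode, carboxysome, clade,
    host_temperature_C, subset_*).  When ``meta_path`` is given, the two
    tables are joined on ``variant_id`` (inner join; unmatched ids are
    reported via a warning).
    """
    def _read(p, cmap):
        sep = "\t" if str(p).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(p, sep=sep)
        if cmap:
            df = df.rename(columns=cmap)
        return df

    df = _read(path, column_map)
    if meta_path is not None:
        meta = _read(meta_path, meta_column_map)
        if "variant_id" not in meta.columns:
            raise ParseError(f"{meta_path}: missing 'variant_id' column")
        if meta["variant_id"].duplicated().any():
            dup = meta.loc[meta["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ParseError(f"{meta_path}: duplicate variant id {dup!r}")
        only_rates = set(df["variant_id"]) - set(meta["variant_id"])
        only_meta = set(meta["variant_id"]) - set(df["variant_id"])
        if only_rates or only_meta:
            warnings.warn(
                f"panel join: {len(only_rates)} rate-only and "
                f"{len(only_meta)} metadata-only variant ids dropped")
        df = df.merge(meta, on="variant_id", how="inner")

    missing = [c for c in PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ParseError(f"{path}: duplicate variant id {dup!r}")
    kcat = pd.to_numeric(df["kcat"], errors="coerce")
    bad = df.index[kcat.isna()]
    if len(bad):
        raise ParseError(
            f"{path}: non-numeric kcat at data row {int(bad[0]) + 2}")
    df["kcat"] = kcat
    if (df["kcat"] < 0).any():
        row = int(df.index[df["kcat"] < 0][0]) + 2
        raise ParseError(f"{path}: negative kcat at row {row}")
    df = _normalize_labels(df, path)
    if "active" not in df.columns:
        df["active"] = df["kcat"] > ACTIVITY_THRESHOLD_KCAT
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences


def write_fasta(records, path) -> None:
    """Write :class:`SequenceRecord` objects as 60-column-wrapped FASTA."""
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id,
                     description=" ".join(sorted(r.subset_tags)))
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fasta(path) -> list:
    """Read FASTA into :class:`SequenceRecord`; description words become
    subset tags."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(maxsplit=1)
        tags = frozenset(desc[1].split()) if len(desc) > 1 else frozenset()
        out.append(SequenceRecord(rec.id, str(rec.seq).upper(), tags))
    return out


# ---------------------------------------------------------------------------
# kinetic results


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "sample_id": r.sample_id,
            "v0_nM_s": r.v0_nM_s,
            "site_conc_nM": r.site_conc_nM,
            "kcat_s": r.kcat_s,
            "active": r.active,
            "qc_flags": ";".join(sorted(r.qc_flags)),
        })
    return pd.DataFrame(rows)


def write_results_tsv(results, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")


# ---------------------------------------------------------------------------
# configuration


KNOWN_CONFIG_KEYS = {
    "seed", "outdir", "constants", "window_policy", "thresholds",
    "panel_groups", "inactive_fraction", "clustering_scheme", "statistics",
    "attribution", "traces_csv", "panel_tsv", "n_sites_nM", "noise_fraction",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    seed: int = 1
    outdir: str = "rubikit_out"
    constants: AssayConstants = field(default_factory=AssayConstants)
    window_policy: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: {
        "activity_kcat": ACTIVITY_THRESHOLD_KCAT,
        "saturation_frac": 0.8,
        "reference_deviation": 0.2,
    })
    panel_groups: list | None = None  # None -> default five-group panel
    inactive_fraction: float = 0.0
    clustering_scheme: list = field(default_factory=list)
    statistics: dict = field(default_factory=lambda: {
        "adjust": "holm",
    })
    attribution: dict = field(default_factory=lambda: {
        "n_splits": 100, "max_depth": 3, "min_leaf": 2, "seed": 42,
        "train_frac": 0.75, "trees_per_split": 1,
    })
    traces_csv: str | None = None  # use existing traces instead of simulating
    panel_tsv: str | None = None
    n_sites_nM: float = 50.0
    noise_fraction: float = 0.02

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - KNOWN_CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "constants" in kwargs:
            kwargs["constants"] = AssayConstants(**kwargs["constants"])
        return cls(**kwargs)

    def canonical_json(self) -> str:
        d = asdict(self)
        d["constants"]["cabp_ladder_nM"] = list(
            d["constants"]["cabp_ladder_nM"])
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def load_constants(path) -> AssayConstants:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AssayConstants(**raw)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> fit-kinetics -> compare-groups ->
    attribute, writing result tables and a reproducibility manifest.

    Stage failures are recorded in the manifest and dependent stages are
    skipped; only configuration/input errors raise.
    """
    from .stats import compare_groups
    from .attribution import run_attribution
    from .synthetic import (TruthRecord, default_panel_groups,
                            simulate_panel, simulate_titration_series,
                            trace_noise_sd)
    from .titration import compute_kcat
    from .traces import WindowPolicy

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical_json()),
        "stages": {},
        "outputs": [],
    }
    policy = WindowPolicy(**config.window_policy)
    rng_seed = config.seed

    # --- stage 1: panel (+ traces) ---------------------------------------
    panel = None
    series_list = []
    try:
        if config.panel_tsv:
            panel = read_panel(config.panel_tsv)
            manifest["stages"]["panel"] = {"status": "loaded",
                                           "path": config.panel_tsv}
        else:
            groups = config.panel_groups or default_panel_groups()
            panel, truths = simulate_panel(
                groups, seed=rng_seed,
                inactive_fraction=config.inactive_fraction,
                activity_threshold=config.thresholds["activity_kcat"])
            if config.traces_csv is None:
                for i, truth in enumerate(truths):
                    noisy = TruthRecord(
                        variant_id=truth.variant_id,
                        kcat_true=truth.kcat_true,
                        site_conc_true_nM=config.n_sites_nM,
                        noise_sd=trace_noise_sd(
                            truth.kcat_true, config.n_sites_nM,
                            config.constants, config.noise_fraction),
                    )
                    series_list.append(simulate_titration_series(
                        noisy, config.constants, seed=rng_seed + 1000 + i))
                write_traces_csv(series_list, outdir / "traces.csv")
                manifest["outputs"].append("traces.csv")
            manifest["stages"]["panel"] = {
                "status": "simulated", "n_variants": int(len(panel))}
    except Exception as exc:
        manifest["stages"]["panel"] = {"status": "failed", "error": str(exc)}
        _write_manifest(manifest, outdir)
        raise

    if config.traces_csv:
        traces = read_traces_csv(config.traces_csv)
        series_list = group_traces_into_series(traces, config.constants)

    # --- stage 2: kinetics ------------------------------------------------
    fitted = None
    if series_list:
        try:
            results = [
                compute_kcat(
                    s, policy,
                    activity_threshold=config.thresholds["activity_kcat"],
                    saturation_frac=config.thresholds["saturation_frac"])
                for s in series_list
            ]
            write_results_tsv(results, outdir / "kinetics.tsv")
            manifest["outputs"].append("kinetics.tsv")
            fitted = {r.sample_id: r for r in results}
            manifest["stages"]["kinetics"] = {
                "status": "ok", "n_samples": len(results),
                "n_active": sum(r.active for r in results),
                "qc_flag_counts": _flag_counts(results),
            }
            # measured kcats replace truth in the panel when both exist
            if panel is not None and set(panel["variant_id"]) <= set(fitted):
                panel = panel.copy()
                panel["kcat"] = [
                    fitted[v].kcat_s if fitted[v].kcat_s is not None else 0.0
                    for v in panel["variant_id"]]
                panel["active"] = [fitted[v].active
                                   for v in panel["variant_id"]]
        except Exception as exc:
            manifest["stages"]["kinetics"] = {"status": "failed",
                                              "error": str(exc)}

    if panel is not None:
        write_panel(panel.round(6), outdir / "panel.tsv")
        manifest["outputs"].append("panel.tsv")

    # --- stage 3: group statistics ---------------------------------------
    if panel is not None and manifest["stages"].get("kinetics", {}).get(
            "status") != "failed":
        try:
            comps = compare_groups(
                panel,
                activity_threshold=config.thresholds["activity_kcat"],
                adjust=config.statistics.get("adjust", "holm"))
            report = {name: c.to_dict() for name, c in comps.items()}
            with open(outdir / "group_comparisons.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            manifest["outputs"].append("group_comparisons.json")
            manifest["stages"]["group_stats"] = {
                "status": "ok", "comparisons": sorted(report)}
        except Exception as exc:
            manifest["stages"]["group_stats"] = {"status": "failed",
                                                 "error": str(exc)}
    else:
        manifest["stages"]["group_stats"] = {"status": "skipped"}

    # --- stage 4: attribution --------------------------------------------
    if panel is not None and manifest["stages"].get("group_stats", {}).get(
            "status") == "ok":
        try:
            report = run_attribution(
                panel,
                activity_threshold=config.thresholds["activity_kcat"],
                **config.attribution)
            with open(outdir / "shap_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            manifest["outputs"].append("shap_report.json")
            manifest["stages"]["attribution"] = {
                "status": "ok", "ranking": report.ranking()}
        except Exception as exc:
            manifest["stages"]["attribution"] = {"status": "failed",
                                                 "error": str(exc)}
    else:
        manifest["stages"]["attribution"] = {"status": "skipped"}

    _write_manifest(manifest, outdir)
    return manifest


def _flag_counts(results) -> dict:
    counts: dict[str, int] = {}
    for r in results:
        for f in r.qc_flags:
            counts[f] = counts.get(f, 0) + 1
    return counts


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
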