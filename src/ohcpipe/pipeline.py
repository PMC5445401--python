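"""Stage orchestration: file-driven runs of each analysis step.

Each stage reads plain-text inputs, computes, and writes its outputs
atomically (temp file in the target directory, then rename) together with
a JSON provenance sidecar carrying the package version, the seed and a
hash of the stage parameters. Outputs are byte-deterministic under a fixed
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cluster import OverlapClustering
from .genesets import build_gene_sets, write_gene_sets_tsv, write_gene_sets_gmt
from .growth import GrowthCurveModel, compare_doubling_times
from .io import (
    read_expression_matrix,
    read_sample_sheet,
    write_distance_matrix,
    write_expression_matrix,
    write_sample_sheet,
)
from .phenotype import (
    DomeRecord,
    TerRecord,
    dome_geneset_association,
    dome_summary,
    ter_summary,
)
from .sam import SamDE
from .simulate import (
    STUDY_DOME_RATES,
    STUDY_DOUBLING_TIMES_H,
    STUDY_TER_DAILY_MEANS,
    SimulationConfig,
    LineSpec,
    simulate_expression,
    simulate_growth,
    simulate_phenotype,
)

logger = logging.getLogger("ohcpipe")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "geneset": {"threshold": 2.0, "mode": "up", "per_line": False},
    "cluster": {"ward_variant": "squared", "k": 2},
    "de": {"n_perm": 1000, "comparisons": [["MT1E", "MT1E-CT"]]},
    "growth": {"min_window": 3},
    "association": {"top_n": 16},
    "simulation": {},
}


def merge_config(overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (overrides or {}).items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _params_hash(params: Mapping[str, Any]) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_provenance(outdir: Path, stage: str, seed: int, params: Mapping[str, Any]) -> None:
    meta = {
        "stage": stage,
        "tool": "ohcpipe",
        "version": __version__,
        "seed": seed,
        "params_hash": _params_hash(params),
    }
    _atomic_write(
        outdir / f"{stage}.provenance.json",
        lambda p: p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n"),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: Mapping[str, Any], outdir: str | os.PathLike) -> Path:
    """Simulate the full study replica: expression, growth, phenotype."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sim_kwargs = dict(cfg.get("simulation") or {})
    if "lines" in sim_kwargs:
        sim_kwargs["lines"] = [LineSpec(**l) for l in sim_kwargs["lines"]]
    sim = SimulationConfig(seed=seed, **sim_kwargs)
    matrix, sheet, truth = simulate_expression(sim)
    _atomic_write(outdir / "matrix.tsv", lambda p: write_expression_matrix(matrix, p))
    _atomic_write(outdir / "samples.tsv", lambda p: write_sample_sheet(sheet, p))
    _atomic_write(outdir / "truth.json", lambda p: truth.to_json(p))

    # growth curves: triplicate wells per line at the study doubling times
    rows = []
    t_points = np.arange(0.0, 169.0, 24.0)
    for i, line in enumerate(sheet.cell_lines):
        td = STUDY_DOUBLING_TIMES_H.get(line, 40.0)
        curve, _ = simulate_growth(
            td, t_points, lag=24.0, plateau_level=2.0, noise_sd=0.01,
            seed=seed * 1009 + i, a0=0.05, n_wells=3,
        )
        for ti, t in enumerate(curve.time_h):
            for w in range(curve.absorbance.shape[1]):
                rows.append((line, t, f"w{w + 1}", curve.absorbance[ti, w]))
        truth.doubling_times_h[line] = td
    growth_frame = pd.DataFrame(rows, columns=["cell_line", "time_h", "well", "absorbance"])
    _atomic_write(
        outdir / "growth.tsv",
        lambda p: growth_frame.to_csv(p, sep="\t", index=False, lineterminator="\n",
                                      float_format="%.6g"),
    )

    # phenotype tables
    dome_rows, ter_rows = [], []
    for i, line in enumerate(sheet.cell_lines):
        rate = STUDY_DOME_RATES.get(line, 0.0)
        ter_means = STUDY_TER_DAILY_MEANS.get(line, 35.0)
        domes, ters, _ = simulate_phenotype(
            rate, n_flasks=3, ter_mean=ter_means, ter_sd=6.0,
            seed=seed * 2003 + i, line=line,
        )
        for rec in domes:
            for fi, c in enumerate(rec.counts):
                dome_rows.append((line, rec.flask_id, fi + 1, c))
        for rec in ters:
            for ri, r in enumerate(rec.readings_ohm):
                ter_rows.append(
                    (line, rec.filter_id, rec.day, ri + 1, r, rec.blank_ohm, rec.area_cm2)
                )
    dome_frame = pd.DataFrame(dome_rows, columns=["cell_line", "flask", "field_index", "count"])
    ter_frame = pd.DataFrame(
        ter_rows,
        columns=["cell_line", "filter", "day", "reading_index", "resistance_ohm",
                 "blank_ohm", "area_cm2"],
    )
    _atomic_write(
        outdir / "domes.tsv",
        lambda p: dome_frame.to_csv(p, sep="\t", index=False, lineterminator="\n"),
    )
    _atomic_write(
        outdir / "ter.tsv",
        lambda p: ter_frame.to_csv(p, sep="\t", index=False, lineterminator="\n",
                                   float_format="%.6g"),
    )
    _atomic_write(outdir / "truth.json", lambda p: truth.to_json(p))
    _write_provenance(outdir, "simulate", seed, cfg)
    logger.info("simulate: wrote study replica to %s", outdir)
    return outdir


def _load_inputs(indir: Path):
    matrix = read_expression_matrix(indir / "matrix.tsv")
    sheet = read_sample_sheet(indir / "samples.tsv")
    sheet.validate_against(matrix)
    return matrix, sheet


def run_genesets(config: Mapping[str, Any], indir, outdir) -> Path:
    cfg = merge_config(config)
    indir, outdir = Path(indir), Path(outdir)
    matrix, sheet = _load_inputs(indir)
    gcfg = cfg["geneset"]
    sets = build_gene_sets(
        matrix, sheet, threshold=float(gcfg["threshold"]), mode=gcfg["mode"],
        per_line=bool(gcfg.get("per_line", False)),
    )
    _atomic_write(outdir / "gene_sets.tsv", lambda p: write_gene_sets_tsv(sets, p))
    _atomic_write(outdir / "gene_sets.gmt", lambda p: write_gene_sets_gmt(sets, p))
    _write_provenance(outdir, "genesets", int(cfg["seed"]), gcfg)
    logger.info("genesets: %d sets written", len(sets))
    return outdir


def run_cluster(config: Mapping[str, Any], indir, outdir) -> Path:
    cfg = merge_config(config)
    indir, outdir = Path(indir), Path(outdir)
    matrix, sheet = _load_inputs(indir)
    gcfg, ccfg = cfg["geneset"], cfg["cluster"]
    sets = build_gene_sets(
        matrix, sheet, threshold=float(gcfg["threshold"]), mode=gcfg["mode"],
        per_line=bool(gcfg.get("per_line", False)),
    )
    res = OverlapClustering(sets, variant=ccfg["ward_variant"]).fit()
    _atomic_write(outdir / "distance.tsv", lambda p: write_distance_matrix(res.distance_, p))
    _atomic_write(outdir / "dendrogram.nwk", lambda p: p.write_text(res.to_newick() + "\n"))
    _atomic_write(
        outdir / "linkage.tsv",
        lambda p: res.linkage_table().to_csv(p, sep="\t", index=False,
                                             lineterminator="\n", float_format="%.10g"),
    )
    k = int(ccfg.get("k", 2))
    labels = res.cut(k).rename("cluster").rename_axis("array_id").reset_index()
    _atomic_write(
        outdir / f"clusters_k{k}.tsv",
        lambda p: labels.to_csv(p, sep="\t", index=False, lineterminator="\n"),
    )
    _write_provenance(outdir, "cluster", int(cfg["seed"]), {**gcfg, **ccfg})
    return outdir


def run_de(config: Mapping[str, Any], indir, outdir) -> Path:
    cfg = merge_config(config)
    indir, outdir = Path(indir), Path(outdir)
    matrix, sheet = _load_inputs(indir)
    dcfg = cfg["de"]
    seed = int(cfg["seed"])
    for line_a, line_b in dcfg["comparisons"]:
        res = SamDE.from_matrix(matrix, sheet, line_a, line_b).fit(
            n_perm=int(dcfg["n_perm"]), seed=seed
        )
        stem = f"de_{line_a}_vs_{line_b}"
        meta = {
            "s0": res.s0_,
            "groups": [str(g) for g in res.groups_],
            **res.perm_meta_,
        }
        _atomic_write(outdir / f"{stem}.tsv", lambda p, r=res: r.to_tsv(p))
        _atomic_write(
            outdir / f"{stem}.meta.json",
            lambda p, m=meta: p.write_text(json.dumps(m, indent=2, sort_keys=True) + "\n"),
        )
    _write_provenance(outdir, "de", seed, dcfg)
    return outdir


def run_growth(config: Mapping[str, Any], indir, outdir) -> Path:
    cfg = merge_config(config)
    indir, outdir = Path(indir), Path(outdir)
    frame = pd.read_csv(indir / "growth.tsv", sep="\t")
    min_window = int(cfg["growth"]["min_window"])
    estimates: dict[str, list[float]] = {}
    rows = []
    for line, grp in frame.groupby("cell_line", sort=False):
        # one estimate per well (replicate culture)
        for well, sub in grp.groupby("well", sort=False):
            sub = sub.sort_values("time_h", kind="mergesort")
            model = GrowthCurveModel.from_dataframe(
                sub.assign(well="w"), min_window=min_window
            )
            fit = model.fit()
            estimates.setdefault(line, []).append(fit.td_hours)
            s = fit.summary()
            rows.append((line, well, *s.to_list()))
    est_frame = pd.DataFrame(
        rows,
        columns=["cell_line", "well", "td_hours", "slope_log2_per_h", "r_squared",
                 "window_start", "window_end", "se_td_hours"],
    )
    _atomic_write(
        outdir / "doubling_times.tsv",
        lambda p: est_frame.to_csv(p, sep="\t", index=False, lineterminator="\n",
                                   float_format="%.6g"),
    )
    comparable = {k: v for k, v in estimates.items() if len(v) >= 2}
    if len(comparable) >= 2:
        tukey = compare_doubling_times(comparable)
        payload = {
            "anova_f": tukey.attrs["anova_f"],
            "anova_p": tukey.attrs["anova_p"],
        }
        _atomic_write(
            outdir / "growth_comparison.tsv",
            lambda p: tukey.to_csv(p, sep="\t", index=False, lineterminator="\n"),
        )
        _atomic_write(
            outdir / "growth_anova.json",
            lambda p: p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n"),
        )
    _write_provenance(outdir, "growth", int(cfg["seed"]), cfg["growth"])
    return outdir


def run_phenotype(config: Mapping[str, Any], indir, outdir,
                  de_dir: str | os.PathLike | None = None) -> Path:
    cfg = merge_config(config)
    indir, outdir = Path(indir), Path(outdir)
    seed = int(cfg["seed"])
    domes = pd.read_csv(indir / "domes.tsv", sep="\t")
    ter = pd.read_csv(indir / "ter.tsv", sep="\t")

    dome_rows, flags = [], {}
    for line, grp in domes.groupby("cell_line", sort=False):
        records = []
        for flask, sub in grp.groupby("flask", sort=False):
            sub = sub.sort_values("field_index", kind="mergesort")
            records.append(DomeRecord(flask_id=str(flask), counts=tuple(sub["count"])))
        summ = dome_summary(records)
        flags[line] = summ.dome_positive
        dome_rows.append((line, summ.mean_per_field, summ.mean_per_21_fields,
                          summ.dome_positive))
    dome_out = pd.DataFrame(
        dome_rows, columns=["cell_line", "mean_per_field", "mean_per_21_fields",
                            "dome_positive"],
    )
    _atomic_write(
        outdir / "dome_summary.tsv",
        lambda p: dome_out.to_csv(p, sep="\t", index=False, lineterminator="\n",
                                  float_format="%.6g"),
    )

    ter_rows = []
    for line, grp in ter.groupby("cell_line", sort=False):
        records = []
        for (flt, day), sub in grp.groupby(["filter", "day"], sort=False):
            sub = sub.sort_values("reading_index", kind="mergesort")
            records.append(
                TerRecord(
                    filter_id=str(flt), day=int(day),
                    readings_ohm=tuple(sub["resistance_ohm"]),
                    blank_ohm=float(sub["blank_ohm"].iloc[0]),
                    area_cm2=float(sub["area_cm2"].iloc[0]),
                )
            )
        table = ter_summary(records)
        row = {"cell_line": line, "combined": table.attrs["combined"]}
        for _, r in table.iterrows():
            row[f"day{int(r['day'])}_mean"] = r["mean"]
            row[f"day{int(r['day'])}_sem"] = r["sem"]
        ter_rows.append(row)
    ter_out = pd.DataFrame(ter_rows)
    _atomic_write(
        outdir / "ter_summary.tsv",
        lambda p: ter_out.to_csv(p, sep="\t", index=False, lineterminator="\n",
                                 float_format="%.6g"),
    )

    # association of the dome phenotype with expression of a probe set:
    # the top-n probes (by q, then |d|) from the first DE comparison
    association = None
    if de_dir is not None and len(set(flags.values())) == 2:
        de_dir = Path(de_dir)
        de_files = sorted(de_dir.glob("de_*_vs_*.tsv"))
        if de_files:
            de_tbl = pd.read_csv(de_files[0], sep="\t")
            top_n = int(cfg["association"]["top_n"])
            top = de_tbl.assign(absd=de_tbl["d"].abs()).sort_values(
                ["q", "absd"], ascending=[True, False], kind="mergesort"
            ).head(top_n)
            probes = list(top["probe_id"].astype(str))
            matrix, sheet = _load_inputs(indir)
            expr = {}
            for line in flags:
                arrays = sheet.arrays_for_line(line)
                if arrays:
                    expr[line] = float(
                        matrix.values.loc[probes, arrays].to_numpy().mean()
                    )
            flags_used = {l: flags[l] for l in expr}
            if len(set(flags_used.values())) == 2:
                res = dome_geneset_association(flags_used, expr, seed=seed)
                association = {
                    "probe_set": probes,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "exhaustive": res.exhaustive,
                }
    if association is not None:
        _atomic_write(
            outdir / "dome_association.json",
            lambda p: p.write_text(json.dumps(association, indent=2, sort_keys=True) + "\n"),
        )
    _write_provenance(outdir, "phenotype", seed, cfg["association"])
    return outdir


def run_all(config: Mapping[str, Any], indir, outdir) -> Path:
    """genesets -> cluster -> de -> growth -> phenotype on simulate output."""
    outdir = Path(outdir)
    run_genesets(config, indir, outdir)
    run_cluster(config, indir, outdir)
    run_de(config, indir, outdir)
    run_growth(config, indir, outdir)
    run_phenotype(config, indir, outdir, de_dir=outdir)
    return outdir
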