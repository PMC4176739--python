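"""File formats, quality control, configuration and the pipeline runner.

Conventions, stated once and enforced in tests: VCF positions are 1-based;
all internal indices are 0-based; the ancestry-tract sidecar is a BED-like
TSV in 0-based half-open coordinates.  Phased genotypes are written as VCF
with a '|' separator (allele A as the REF base ``A``, allele B as the ALT
base ``C``); a simpler haplotype-matrix TSV is supported for both directions
as well.  Reading uses cyvcf2; unphased or multi-allelic records are errors.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import MISSING, HaplotypePanel

log = logging.getLogger("origingwas")


# ---------------------------------------------------------------------------
# phased genotypes


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write fully phased biallelic genotypes as VCF 4.2 text."""
    path = Path(path)
    chroms = panel.snp_map["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=origingwas\n")
        for c in chroms:
            maxpos = int(panel.snp_map.loc[panel.snp_map["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in panel.animal_ids)
            + "\n"
        )
        hap = panel.haplotypes
        code = {0: "0", 1: "1", MISSING: "."}
        for j, row in enumerate(panel.snp_map.itertuples(index=False)):
            pat = hap[0::2, j]
            mat = hap[1::2, j]
            gts = "\t".join(f"{code[int(p)]}|{code[int(m)]}" for p, m in zip(pat, mat))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased biallelic VCF into a panel.

    Raises on an unphased heterozygote or a multi-allelic record, naming it;
    drops the later of two records at a duplicated position with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    rows = []
    haps = []
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        key = (var.CHROM, var.POS)
        if key in seen:
            warnings.warn(f"duplicate position {var.CHROM}:{var.POS}; dropping later record")
            continue
        seen.add(key)
        gt = np.array(var.genotypes)  # (n, 3): a0, a1, phased flag
        het = gt[:, 0] != gt[:, 1]
        unphased = (gt[:, 2] == 0) & het & (gt[:, 0] >= 0)
        if np.any(unphased):
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} "
                f"(sample {samples[np.flatnonzero(unphased)[0]]})"
            )
        a = gt[:, :2].astype(np.int8)
        a[a < 0] = MISSING
        rows.append((int(var.CHROM), var.POS, var.ID or f"{var.CHROM}:{var.POS}"))
        haps.append(a.reshape(-1))
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    hap = np.array(haps, dtype=np.int8).T  # (2n, m)
    return HaplotypePanel(snp_map=snp_map, haplotypes=hap, animal_ids=samples)


def write_haplotype_tsv(panel: HaplotypePanel, path: str | Path) -> None:
    """Plain haplotype matrix: map columns then one column per haplotype."""
    names = []
    for a in panel.animal_ids:
        names.extend([f"{a}.p", f"{a}.m"])
    hap_df = pd.DataFrame(panel.haplotypes.T, columns=names)
    df = pd.concat([panel.snp_map[["chrom", "pos", "id"]], hap_df], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path: str | Path) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    hap_cols = [c for c in df.columns if c.endswith((".p", ".m"))]
    animals = []
    for c in hap_cols[0::2]:
        animals.append(c[:-2])
    hap = df[hap_cols].to_numpy(dtype=np.int8).T
    return HaplotypePanel(
        snp_map=df[["chrom", "pos", "id"]].copy(),
        haplotypes=hap,
        animal_ids=np.array(animals, dtype=object),
    )


def write_tracts(tracts: pd.DataFrame, path: str | Path) -> None:
    tracts.to_csv(path, sep="\t", index=False)


def write_phenotypes(phen: pd.DataFrame, path: str | Path) -> None:
    phen.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QcReport:
    n_snps_in: int
    n_animals_in: int
    snps_removed_call_rate: int = 0
    snps_removed_hwe: int = 0
    snps_removed_duplicate: int = 0
    animals_removed_call_rate: int = 0

    @property
    def n_snps_out(self) -> int:
        return (self.n_snps_in - self.snps_removed_call_rate
                - self.snps_removed_hwe - self.snps_removed_duplicate)

    @property
    def n_animals_out(self) -> int:
        return self.n_animals_in - self.animals_removed_call_rate


def apply_qc(panel: HaplotypePanel, call_rate: float = 0.90) -> tuple[HaplotypePanel, QcReport]:
    """Remove low-call-rate SNPs and animals and HWE-degenerate SNPs.

    A SNP fails the Hardy-Weinberg degeneracy rule when both homozygous
    genotype classes are observed but no heterozygote is — the specific
    extreme-departure pattern excluded from array data.  Animal filtering
    happens after SNP filtering, on the retained SNPs.
    """
    report = QcReport(n_snps_in=panel.n_snps, n_animals_in=panel.n_animals)
    d = panel.dosage()  # NaN where missing
    called = np.isfinite(d)
    snp_call = called.mean(axis=0)
    keep_snp = snp_call >= call_rate
    report.snps_removed_call_rate = int((~keep_snp).sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_aa = np.nansum(d == 0, axis=0)
        n_ab = np.nansum(d == 1, axis=0)
        n_bb = np.nansum(d == 2, axis=0)
    hwe_bad = (n_aa > 0) & (n_bb > 0) & (n_ab == 0)
    report.snps_removed_hwe = int((hwe_bad & keep_snp).sum())
    keep_snp &= ~hwe_bad

    panel = panel.subset_snps(keep_snp)
    d = d[:, keep_snp]
    animal_call = np.isfinite(d).mean(axis=1)
    keep_an = animal_call >= call_rate
    report.animals_removed_call_rate = int((~keep_an).sum())
    panel = panel.subset_animals(keep_an)
    return panel, report


# ---------------------------------------------------------------------------
# configuration and pipeline


@dataclass
class RunConfig:
    out_dir: str = "origingwas_out"
    genotypes: str | None = None  # None => simulate
    phenotypes: str | None = None
    segment_size: int = 30
    smoothing_window: int = 7
    origin_threshold: float = 0.6
    models: tuple[str, ...] = ("conventional", "interaction", "best_variable")
    thresholds: tuple[float, ...] = (1e-4, 1e-6, 5e-8)
    use_grm: bool = True
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self):
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if not 0.0 < self.origin_threshold < 1.0:
            raise ValueError("origin_threshold must lie in (0, 1)")
        for t in self.thresholds:
            if not 0.0 < t < 1.0:
                raise ValueError("significance thresholds must lie in (0, 1)")
        for m in self.models:
            if m not in ("conventional", "interaction", "best_variable"):
                raise ValueError(f"unknown model tag {m!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("models", "thresholds"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["models"] = list(d["models"])
    d["thresholds"] = [float(t) for t in d["thresholds"]]
    return d


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """simulate (optional) -> QC -> ancestry -> GWAS -> report.

    Writes every intermediate table under ``config.out_dir`` together with a
    manifest recording the seed, config hash and stage timings.  Any stage
    failure propagates with a stage-tagged message; earlier outputs remain.
    """
    from . import __version__
    from .ancestry import ancestry_fraction_report, infer_ancestry
    from .assoc import GwasDataset, run_best_variable_gwas, run_conventional_gwas, \
        run_interaction_gwas, vanraden_grm
    from .report import classify_patterns, fdr_table, pattern_counts, select_top_snps
    from .simpop import SimulationConfig, simulate_dataset

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "stages": {},
    }
    save_config(config, out / "config.yaml")

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = round(time.time() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done (%.2fs)", name, manifest["stages"][name])

        return _Stage()

    with stage("simulate"):
        if config.genotypes is None:
            sim_cfg = SimulationConfig(**({"seed": config.seed} | config.simulate))
            sim = simulate_dataset(sim_cfg)
            panel, groups, phen = sim.panel, sim.groups, sim.phenotypes
            ref_t, ref_i = sim.taurus, sim.indicus
            write_vcf(panel, out / "genotypes.vcf")
            write_tracts(sim.truth.tracts, out / "true_tracts.tsv")
            write_phenotypes(phen, out / "phenotypes.tsv")
        else:
            panel = read_vcf(config.genotypes)
            phen = read_phenotypes(config.phenotypes)
            phen = phen.set_index("animal_id").loc[panel.animal_ids].reset_index()
            groups = phen["group"].to_numpy()
            ref_t = panel.subset_animals(groups == "taurus", group="taurus")
            ref_i = panel.subset_animals(groups == "indicus", group="indicus")

    with stage("qc"):
        panel_qc, qc = apply_qc(panel)
        kept = panel.snp_map["id"].isin(panel_qc.snp_map["id"]).to_numpy()
        ref_t = ref_t.subset_snps(kept)
        ref_i = ref_i.subset_snps(kept)
        keep_animals = pd.Index(panel_qc.animal_ids)
        phen = phen[phen["animal_id"].isin(keep_animals)].reset_index(drop=True)
        groups = phen["group"].to_numpy()
        (out / "qc_report.json").write_text(json.dumps(dataclasses.asdict(qc), indent=2))
        panel = panel_qc

    with stage("ancestry"):
        origins, aom = infer_ancestry(
            panel, ref_t, ref_i,
            segment_size=config.segment_size,
            window=config.smoothing_window,
            threshold=config.origin_threshold,
        )
        per_animal, per_group, _ = ancestry_fraction_report(origins, groups)
        per_animal.assign(animal_id=panel.animal_ids).to_csv(
            out / "ancestry_fractions.tsv", sep="\t", index=False
        )
        per_group.to_csv(out / "ancestry_group_fractions.tsv", sep="\t", index=False)
        b_rows = []
        for h in range(origins.raw_b.shape[0]):
            for j, seg in enumerate(origins.segments):
                b_rows.append((h, seg.chromosome, j, origins.raw_b[h, j],
                               origins.smoothed_b[h, j], int(origins.labels[h, j])))
        pd.DataFrame(
            b_rows, columns=["hap_id", "chrom", "segment", "raw_b", "smoothed_b", "label"]
        ).to_csv(out / "segment_b.tsv", sep="\t", index=False)

    with stage("gwas"):
        grm = vanraden_grm(panel.dosage()) if config.use_grm else None
        ds = GwasDataset(aom=aom, phenotypes=phen, groups=groups, grm=grm)
        results = {}
        if "conventional" in config.models:
            frames = [run_conventional_gwas(ds, "all")]
            for sub in np.unique(groups):
                frames.append(run_conventional_gwas(ds, str(sub)))
            results["conventional"] = pd.concat(frames, ignore_index=True)
        if "interaction" in config.models:
            results["interaction"] = run_interaction_gwas(ds)
        if "best_variable" in config.models:
            results["best_variable"] = run_best_variable_gwas(ds)
        for name, df in results.items():
            df.to_csv(out / f"gwas_{name}.tsv", sep="\t", index=False)

    with stage("report"):
        p0 = config.thresholds[0]
        if "conventional" in results:
            fdr_table(results["conventional"], "p_x1", p0).to_csv(
                out / "fdr.tsv", sep="\t", index=False
            )
        if "interaction" in results:
            pats = classify_patterns(results["interaction"], p0)
            pats.to_csv(out / "patterns.tsv", sep="\t", index=False)
            pattern_counts(pats).rename("count").to_csv(out / "pattern_counts.tsv", sep="\t")
        if "best_variable" in results:
            top = select_top_snps(results["best_variable"], p0)
            top.to_csv(out / "top_snps.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
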