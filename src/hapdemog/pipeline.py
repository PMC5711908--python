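"""End-to-end reproducible runs: config, stage seeds, manifest.

A run executes haplotyping -> diversity -> network -> mismatch and,
when the corresponding inputs are configured, the AFLP and RDA stages.
Every stochastic stage derives its seed from the global seed plus the
stage name by stable hashing, so adding or removing a stage never
perturbs another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aflp as aflp_mod
from . import demography, network, popgen, rda, seqio


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1) + 1


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    alignment: str | None = None
    metadata: str | None = None
    min_run: int = 3
    group_by: str = "region"
    exclude_haplotypes: dict = field(default_factory=dict)
    alpha: float = 0.95
    mu: float = 2.004e-9
    seq_len: int = 1512
    gen_time: float = 2.0
    bootstrap: int = 1000
    mismatch_groups: list = field(default_factory=list)
    aflp_matrix: str | None = None
    aflp_metadata: str | None = None
    aflp_replicates: str | None = None
    filter_ref_year: int = 2003
    k_sigma: float = 2.0
    rda_alpha: float = 0.01
    n_perm: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def validate(self):
        if self.alignment is not None and self.metadata is None:
            raise seqio.InputError("alignment configured without metadata")
        for attr in ("alignment", "metadata", "aflp_matrix", "aflp_metadata",
                     "aflp_replicates"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise seqio.InputError(f"{attr} file not found: {p}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "min_run": config.min_run, "mu": config.mu, "k": config.seq_len,
            "g": config.gen_time, "bootstrap": config.bootstrap,
            "alpha": config.alpha, "n_perm": config.n_perm,
            "time_convention": "per-year (T = tau / (2 mu k g))",
        },
        "stages": {},
        "outputs": {},
    }
    log_lines = [f"hapdemog {__version__} seed={config.seed}"]

    if config.alignment:
        stage = "haplotypes"
        aln = seqio.read_alignment(config.alignment, config.metadata)
        aln = seqio.mask_homopolymer_variation(aln, min_run=config.min_run)
        hset = seqio.collapse_haplotypes(aln)
        hset.to_frame().to_csv(out / "haplotypes.tsv", sep="\t", index=False)
        freq = seqio.frequency_table(hset, aln, group_by=config.group_by)
        freq.to_csv(out / "haplotype_frequencies.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_samples": aln.n, "L": aln.length,
            "n_haplotypes": hset.n_haplotypes,
            "masked_columns": int(aln.masked.sum()),
        }
        log_lines.append(
            f"[haplotypes] {aln.n} samples, L={aln.length}, "
            f"{hset.n_haplotypes} haplotypes, {int(aln.masked.sum())} masked columns"
        )

        stats = popgen.group_summary(
            aln, hset, grouping=config.group_by,
            exclude_haplotypes=config.exclude_haplotypes,
        )
        popgen.summary_frame(stats).to_csv(
            out / "diversity.tsv", sep="\t", index=False
        )
        manifest["stages"]["diversity"] = {"groups": [s.group for s in stats]}
        log_lines.append(f"[diversity] {len(stats)} groups")

        j95 = network.connection_limit(aln.length, alpha=config.alpha)
        dmat = network.pairwise_difference_matrix(hset)
        net = network.build_network(hset, dmat, j95)
        net.edge_list().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            "j95": j95, "components": len(net.components()),
            "inferred_nodes": len(net.inferred_nodes),
        }
        log_lines.append(
            f"[network] connection limit {j95} steps, "
            f"{len(net.components())} component(s)"
        )

        rate = demography.RateModel(mu=config.mu, k=config.seq_len,
                                    g=config.gen_time)
        groups = config.mismatch_groups or [
            g for g in {s.region for s in aln.samples} if g
        ]
        rows = []
        for gname in sorted(groups):
            ids = [s.sample_id for s in aln.samples if s.region == gname]
            if len(ids) < 3:
                continue
            sub = aln.subset(ids)
            h = demography.mismatch_histogram(sub)
            fit = demography.fit_sudden_expansion(h)
            res = demography.parametric_bootstrap(
                h, fit, B=config.bootstrap,
                seed=stage_seed(config.seed, f"mismatch:{gname}"), rate=rate,
            )
            rows.append({
                "group": gname, "n": sub.n, "tau": round(res.tau, 3),
                "theta0": round(res.theta0, 4), "theta1": round(res.theta1, 1),
                "SSD": round(res.SSD, 5), "p_SSD": res.p_SSD,
                "HRag": round(res.HRag, 5), "p_HRag": res.p_HRag,
                "tau_lo": round(res.tau_CI[0], 3),
                "tau_hi": round(res.tau_CI[1], 3),
                "T_years": round(res.T_years, 1),
                "T_lo": round(res.T_years_CI[0], 1),
                "T_hi": round(res.T_years_CI[1], 1),
            })
            log_lines.append(
                f"[mismatch] {gname}: tau={res.tau:.2f} "
                f"({res.tau_CI[0]:.2f}-{res.tau_CI[1]:.2f}), "
                f"T={res.T_years / 1e6:.3f} My, p_SSD={res.p_SSD:.3f}"
            )
        pd.DataFrame(rows).to_csv(out / "mismatch.tsv", sep="\t", index=False)
        manifest["stages"]["mismatch"] = {"groups": [r["group"] for r in rows]}

    if config.aflp_matrix:
        m = aflp_mod.read_aflp(config.aflp_matrix, config.aflp_metadata,
                               config.aflp_replicates)
        info: dict = {"n_samples": m.n, "n_loci": len(m.loci)}
        if m.replicate_pairs:
            err = aflp_mod.replicate_error_rate(m)
            info["replicate_error_rate"] = round(err, 4)
            log_lines.append(f"[aflp] replicate error rate {err:.3%}")
        filtered, report = aflp_mod.fragment_filter(
            m, reference_year=config.filter_ref_year, k_sigma=config.k_sigma
        )
        info["removed"] = report.removed_ids
        log_lines.append(
            f"[aflp] fragment filter removed {len(report.removed_ids)} samples "
            f"(band {report.lower:.1f}-{report.upper:.1f})"
        )
        d = aflp_mod.euclidean_distance(filtered)
        ord_res = aflp_mod.pcoa(d)
        info["positive_eigenvalues"] = ord_res.n_positive
        info["significant_axes"] = (ord_res.significant_axes() + 1).tolist()
        pd.DataFrame(
            ord_res.coordinates,
            index=filtered.sample_ids,
            columns=[f"PCo{i + 1}" for i in range(ord_res.n_positive)],
        ).to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        aflp_mod.band_statistics(filtered).to_csv(
            out / "band_statistics.tsv", sep="\t", index=False
        )
        groups = [s.region for s in filtered.samples]
        am = aflp_mod.amova(
            aflp_mod.euclidean_distance(filtered), groups,
            permutations=config.n_perm,
            seed=stage_seed(config.seed, "amova"),
        )
        info["amova"] = {"phi_st": round(am.phi_st, 4), "p": am.p}
        log_lines.append(f"[aflp] AMOVA Phi_ST={am.phi_st:.3f} p={am.p:.4g}")
        manifest["stages"]["aflp"] = info

        # partial RDA of significant axes on trend-surface terms,
        # conditioned on gene pool (two largest regions)
        sig = ord_res.significant_axes()
        lon = [s.lon for s in filtered.samples]
        lat = [s.lat for s in filtered.samples]
        if sig.size and all(v is not None for v in lon + lat):
            Y = ord_res.coordinates[:, sig]
            spatial = rda.standardize_and_polynomials(lon, lat)
            regions = pd.Series([s.region for s in filtered.samples])
            condition = (regions == regions.mode()[0]).astype(float).to_numpy()
            selected, log = rda.forward_select(
                Y, spatial, Z=condition, alpha=config.rda_alpha,
                n_perm=config.n_perm, seed=stage_seed(config.seed, "rda"),
            )
            X = spatial[selected] if selected else None
            res = rda.partial_rda(Y, X, Z=condition)
            rda_info = {
                "selected_terms": selected,
                "conditional_pct": round(res.conditional_pct, 2),
                "constrained_pct": round(res.constrained_pct, 2),
                "residual_pct": round(res.residual_pct, 2),
            }
            if selected:
                tab = rda.term_table(
                    Y, spatial[selected], Z=condition, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "rda-terms"),
                )
                tab.to_csv(out / "rda_terms.tsv", sep="\t", index=False)
                rda_info["vif"] = {
                    k: round(v, 3)
                    for k, v in rda.vif(spatial[selected], condition).items()
                }
            manifest["stages"]["rda"] = rda_info
            log_lines.append(
                f"[rda] selected {selected}; partition "
                f"{res.conditional_pct:.1f}/{res.constrained_pct:.1f}/"
                f"{res.residual_pct:.1f}%"
            )

    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
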