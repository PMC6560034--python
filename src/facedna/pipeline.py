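"""End-to-end experiment orchestration.

A run partitions the cohort into a training set (shape model, association
scans, classifiers) and three rotation folds of the remainder (two folds
fuse, one tests; rotated so each fold is the test set once), then executes
the stages in order:

1. ``phenotype`` — shape model fitted on training faces only; every face
   projected into the per-segment PC spaces;
2. ``associate`` — scans on training individuals: sex/age/BMI and
   binarized genomic-background PCs against all segments, the additive
   covariate-adjusted GWAS, locus clumping, and dominant/recessive
   re-tests of the peak SNPs;
3. ``train`` — one calibrated face classifier per deployed molecular
   feature on concatenated selected-segment shape features;
4. ``fuse`` — all-vs-all match-score tensors on validation and test
   individuals per rotation;
5. ``evaluate`` — naive-Bayes fusion learned on validation, biometric
   metrics (EER/AUC, rank-x% rates) on test for accumulating feature
   subsets, averaged over the three rotations.

Training, validation and test id sets are disjoint by construction and
asserted at run time; one master seed drives every stage through named
substreams.  A :class:`PipelineRun` can persist after each stage and
resume from the last completed one.
"""

from __future__ import annotations

import json
import logging
import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from facedna._rng import subseed, substream
from facedna import association as assoc_mod
from facedna.biometrics import evaluate_feature_subsets
from facedna.classify import (
    MolecularFeature,
    binarize_feature,
    encode_snp_models,
    orient_minor_allele,
    select_segments,
    train_classifier,
)
from facedna.cohort import (
    PopulationModel,
    SyntheticCohort,
    genomic_background_pcs,
    read_cohort,
    simulate_cohort,
)
from facedna.shape import ShapePhenotyper

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "Partition",
    "make_partition",
    "PipelineRun",
    "run_experiment",
    "ExperimentResult",
]

SUBSET_ORDER = ["sex", "gb", "snps", "bmi", "age"]


@dataclass
class ExperimentConfig:
    """Everything a run needs; YAML-round-trippable."""

    # cohort: either a directory with a written cohort, or simulation sizes
    cohort_dir: str | None = None
    n_individuals: int = 600
    n_panel: int = 300
    n_snps: int = 2000
    n_causal_snps: int = 10
    n_landmarks: int = 250
    n_populations: int = 3
    fst: float = 0.15
    admixture_concentration: float = 0.5
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    effect_scales: dict = field(default_factory=dict)  # see cohort.default_effects
    # shape space
    depth: int = 5
    pa_permutations: int = 100
    pa_percentile: float = 0.95
    # association
    maf_min: float = 0.05
    fdr_alpha: float = 0.05
    segment_p_max: float = 1e-3  # facial-segment selection for classifiers
    n_gwas_pcs: int = 4  # continuous genomic PCs used as GWAS covariates
    clump_window_bp: int = 500_000
    clump_r2_min: float = 0.5
    # classifiers / fusion
    classifier: str = "svm"
    prior_mode: str = "empirical"
    # partitioning
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.segment_p_max <= 1) or not (0 < self.fdr_alpha <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.cohort_dir is not None and not Path(self.cohort_dir).exists():
            raise FileNotFoundError(self.cohort_dir)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Partition:
    """Training ids plus three disjoint folds of the remainder."""

    train_ids: list[str]
    folds: list[list[str]]

    def rotations(self):
        """Yield (rotation index, validation ids, test ids)."""
        for r in range(len(self.folds)):
            val = [i for k, f in enumerate(self.folds) if k != r for i in f]
            yield r, val, list(self.folds[r])

    def validate(self) -> None:
        all_fold = [i for f in self.folds for i in f]
        if len(set(all_fold)) != len(all_fold):
            raise ValueError("folds overlap")
        if set(all_fold) & set(self.train_ids):
            raise ValueError("folds overlap the training set")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            logger.warning("fold sizes uneven: %s", sizes)


def make_partition(ids, train_fraction: float = 0.5, seed: int = 0) -> Partition:
    """Seeded shuffle into a training set and three near-equal folds."""
    ids = [str(i) for i in ids]
    if len(ids) < 30:
        raise ValueError("need at least 30 individuals to partition")
    rng = substream(seed, "partition")
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    shuffled = [ids[i] for i in order]
    train = shuffled[:n_train]
    rest = shuffled[n_train:]
    folds = [rest[k::3] for k in range(3)]
    part = Partition(train_ids=train, folds=folds)
    part.validate()
    return part


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


@dataclass
class ExperimentResult:
    """Summary of a completed run."""

    config: ExperimentConfig
    partition: Partition
    feature_table: pd.DataFrame  # association scan of all binary/continuous features
    feature_fdrd: float
    gwas_table: pd.DataFrame | None
    gwas_fdrd: float
    loci: pd.DataFrame | None
    classifier_inventory: pd.DataFrame
    per_fold: pd.DataFrame  # subset metrics per rotation
    report: pd.DataFrame  # mean/SD across rotations
    runtime_s: float


STAGES = ["simulate", "phenotype", "associate", "train", "fuse", "evaluate"]


class PipelineRun:
    """Stage-by-stage execution with optional on-disk persistence.

    Stages must run in order; ``save``/``load`` pickle the run so a later
    invocation can resume from the last completed stage.  Human-readable
    artifacts (TSV/JSON) are written into the run directory as each stage
    completes.
    """

    def __init__(self, config: ExperimentConfig, outdir=None) -> None:
        self.config = config
        self.outdir = Path(outdir) if outdir is not None else None
        self.completed: list[str] = []
        self.t0 = time.time()
        self.cohort: SyntheticCohort | None = None
        self.partition: Partition | None = None
        self.phenotyper: ShapePhenotyper | None = None
        self.scores_all: dict[int, np.ndarray] | None = None

    # -- persistence --------------------------------------------------

    def save(self) -> None:
        if self.outdir is None:
            return
        self.outdir.mkdir(parents=True, exist_ok=True)
        with open(self.outdir / "state.pkl", "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, outdir) -> "PipelineRun":
        with open(Path(outdir) / "state.pkl", "rb") as fh:
            run = pickle.load(fh)
        run.outdir = Path(outdir)
        return run

    def _require(self, stage: str) -> None:
        order = STAGES.index(stage)
        for earlier in STAGES[:order]:
            if earlier not in self.completed:
                raise RuntimeError(f"stage {stage!r} requires {earlier!r} first")

    def _done(self, stage: str) -> None:
        if stage not in self.completed:
            self.completed.append(stage)
        self.save()

    def _out(self, name: str) -> Path | None:
        if self.outdir is None:
            return None
        self.outdir.mkdir(parents=True, exist_ok=True)
        return self.outdir / name

    # -- stages -------------------------------------------------------

    def stage_simulate(self, cohort: SyntheticCohort | None = None) -> None:
        """Obtain the cohort (given, loaded from disk, or simulated)."""
        cfg = self.config
        if cohort is not None:
            self.cohort = cohort
        elif cfg.cohort_dir is not None:
            logger.info("loading cohort from %s", cfg.cohort_dir)
            self.cohort = read_cohort(cfg.cohort_dir)
        else:
            logger.info("simulating cohort (n=%d)", cfg.n_individuals)
            model = PopulationModel(
                n_populations=cfg.n_populations,
                fst_per_population=(cfg.fst,) * cfg.n_populations,
                admixture_concentration=cfg.admixture_concentration,
            )
            self.cohort = simulate_cohort(
                n_individuals=cfg.n_individuals,
                n_panel=cfg.n_panel,
                n_snps=cfg.n_snps,
                n_causal_snps=cfg.n_causal_snps,
                n_landmarks=cfg.n_landmarks,
                model=model,
                noise_sd=cfg.noise_sd,
                missing_rate=cfg.missing_rate,
                seed=subseed(cfg.seed, "cohort"),
                **cfg.effect_scales,
            )
        if self.cohort.faces is None or self.cohort.template is None:
            raise ValueError("cohort must include faces and a template")
        ids = self.cohort.ids
        self.row_of = {i: r for r, i in enumerate(ids)}
        self.partition = make_partition(ids, cfg.train_fraction, cfg.seed)
        self.train_rows = np.array([self.row_of[i] for i in self.partition.train_ids])
        self._done("simulate")

    def stage_phenotype(self) -> None:
        """Fit the shape model on training faces; project every face."""
        self._require("phenotype")
        cfg = self.config
        logger.info("fitting shape model on %d training faces", len(self.train_rows))
        self.phenotyper = ShapePhenotyper(
            depth=cfg.depth,
            n_permutations=cfg.pa_permutations,
            percentile=cfg.pa_percentile,
            seed=subseed(cfg.seed, "shape"),
        )
        self.phenotyper.fit(self.cohort.faces[self.train_rows], self.cohort.template)
        self.scores_all = self.phenotyper.transform(self.cohort.faces)
        self.train_scores = {s: v[self.train_rows] for s, v in self.scores_all.items()}
        if (p := self._out("segmentation.json")) is not None:
            self.phenotyper.tree.to_json(p)
        self._done("phenotype")

    def stage_associate(self) -> None:
        """Association scans, GWAS, clumping, peak-SNP re-test."""
        self._require("associate")
        cfg = self.config
        cohort = self.cohort
        cov = cohort.covariates
        sex = cov["sex"].to_numpy(float)
        age = cov["age"].to_numpy(float)
        bmi = cov["bmi"].to_numpy(float)
        pc_scores, _ = genomic_background_pcs(
            cohort.genotypes, cohort.reference_genotypes
        )
        self.pc_scores = pc_scores
        tr = self.train_rows

        mol_features: dict[str, MolecularFeature] = {
            "sex": MolecularFeature("sex", "binary", sex, "sex"),
            "age": MolecularFeature("age", "continuous", age, "age", threshold=30.0),
            "bmi": MolecularFeature(
                "bmi", "continuous", bmi, "bmi",
                threshold=float(np.median(bmi[tr])),
            ),
        }
        for k in range(pc_scores.shape[1]):
            mol_features[f"gpc{k + 1}"] = MolecularFeature(
                f"gpc{k + 1}", "continuous", pc_scores[:, k], "genomic_pc",
                threshold=0.0,
            )
        self.binary_all = {}
        for name, mf in mol_features.items():
            bf = binarize_feature(mf)
            if bf is not None:
                self.binary_all[name] = bf

        scan_features = {"sex": sex[tr], "age": age[tr], "bmi": bmi[tr]}
        for name, bf in self.binary_all.items():
            if name.startswith("gpc"):
                scan_features[name] = bf.labels[tr].astype(float)
        self.scan_features = scan_features
        self.feature_table, self.feature_fdrd = assoc_mod.feature_scan(
            scan_features, self.train_scores, covariates=None, alpha=cfg.fdr_alpha
        )
        logger.info("feature scan FDRd threshold: %.3g", self.feature_fdrd)

        gwas_cov = np.column_stack(
            [sex, _zscore(age), _zscore(bmi), pc_scores[:, : cfg.n_gwas_pcs]]
        )[tr]
        self.gwas_cov = gwas_cov
        self.gwas_table, self.gwas_fdrd = assoc_mod.gwas_scan(
            cohort.genotypes[tr],
            cohort.snp_table["id"],
            self.train_scores,
            covariates=gwas_cov,
            maf_min=cfg.maf_min,
            alpha=cfg.fdr_alpha,
        )
        logger.info("GWAS FDRd threshold: %.3g", self.gwas_fdrd)
        best = self.gwas_table.loc[self.gwas_table.groupby("snp")["p"].idxmin()]
        sig = (
            best[best["p"] <= self.gwas_fdrd]
            if self.gwas_fdrd > 0
            else best.iloc[:0]
        )
        sig_tbl = sig.merge(
            cohort.snp_table[["id", "chrom", "pos"]], left_on="snp", right_on="id"
        )[["id", "chrom", "pos", "p"]]
        self.loci = assoc_mod.clump_loci(
            sig_tbl,
            cohort.genotypes[tr],
            list(cohort.snp_table["id"]),
            window_bp=cfg.clump_window_bp,
            ld_r2_min=cfg.clump_r2_min,
        )
        logger.info("%d significant SNPs in %d loci", len(sig_tbl), len(self.loci))

        # dominant/recessive recoding of peak SNPs, re-tested for selection
        snp_index = {s: j for j, s in enumerate(cohort.snp_table["id"])}
        snp_binaries = {}
        for peak in list(self.loci["peak_snp"]) if len(self.loci) else []:
            dos, _ = orient_minor_allele(cohort.genotypes[:, snp_index[peak]])
            mf = MolecularFeature(str(peak), "genotype", dos, "snp")
            for bf in encode_snp_models(mf, orient=False):
                if not bf.degenerate:
                    snp_binaries[bf.name] = bf
        self.snp_scan = {
            name: bf.labels[tr].astype(float)
            for name, bf in snp_binaries.items()
            if len(np.unique(bf.labels[tr])) > 1
        }
        if self.snp_scan:
            snp_assoc, _ = assoc_mod.feature_scan(
                self.snp_scan, self.train_scores,
                covariates=gwas_cov, alpha=cfg.fdr_alpha,
            )
            self.feature_table = pd.concat(
                [self.feature_table, snp_assoc], ignore_index=True
            )
        self.binary_all.update(snp_binaries)

        if (p := self._out("feature_associations.tsv")) is not None:
            self.feature_table.to_csv(p, sep="\t", index=False)
            self.gwas_table.to_csv(self.outdir / "gwas.tsv", sep="\t", index=False)
            loci = self.loci.copy()
            if "member_snps" in loci:
                loci["member_snps"] = loci["member_snps"].map(
                    lambda ms: ",".join(map(str, ms))
                )
            loci.to_csv(self.outdir / "loci.tsv", sep="\t", index=False)
        self._done("associate")

    def stage_train(self) -> None:
        """Deployment decisions and per-feature classifier training."""
        self._require("train")
        cfg = self.config
        min_p = self.feature_table.groupby("feature")["p"].min()
        deployed: dict[str, dict] = {}
        for name in self.scan_features:
            group = "sex" if name == "sex" else (
                "gb" if name.startswith("gpc") else name
            )
            # a feature deploys when some segment reaches the pooled FDRd
            if name not in min_p.index or min_p[name] > self.feature_fdrd:
                continue
            segs = select_segments(self.feature_table, name, cfg.segment_p_max)
            if not segs:
                continue
            deployed[name] = {"group": group, "segments": segs}
        for name in self.snp_scan:
            segs = select_segments(self.feature_table, name, cfg.segment_p_max)
            if segs:
                deployed[name] = {"group": "snps", "segments": segs}
        self.deployed = deployed

        classifiers = {}
        inventory_rows = []
        tr = self.train_rows
        for name, meta in deployed.items():
            bf = self.binary_all[name]
            segs = meta["segments"]
            X = np.column_stack([self.train_scores[s] for s in segs])
            y_train = bf.labels[tr]
            if np.bincount(y_train, minlength=2).min() < 5:
                logger.info("feature %s: too few instances per class", name)
                continue
            sub_bf = type(bf)(
                name=bf.name, labels=y_train, source=bf.source,
                threshold_used=bf.threshold_used,
                inheritance_model=bf.inheritance_model,
            )
            clf = train_classifier(
                X, sub_bf, seed=subseed(cfg.seed, f"train-{name}"),
                kind=cfg.classifier, segments=segs,
            )
            classifiers[name] = clf
            inventory_rows.append(
                {
                    "feature": name, "group": meta["group"],
                    "n_segments": len(segs), "n_dims": X.shape[1],
                    "inheritance": bf.inheritance_model,
                    "train_balanced_accuracy": clf.training_balanced_accuracy,
                }
            )
        self.classifiers = classifiers
        self.classifier_inventory = pd.DataFrame(inventory_rows)
        self.feature_order = list(classifiers)
        logger.info("deployed %d classifiers", len(classifiers))
        if (p := self._out("classifiers.tsv")) is not None:
            self.classifier_inventory.to_csv(p, sep="\t", index=False)
        self._done("train")

    def stage_fuse(self) -> None:
        """Posteriors for all non-training faces; match-score tensors."""
        self._require("fuse")
        part = self.partition
        ids = self.cohort.ids
        nontrain_ids = [i for i in ids if i not in set(part.train_ids)]
        self.nontrain_ids = nontrain_ids
        nt_rows = np.array([self.row_of[i] for i in nontrain_ids])
        self.nt_pos = {i: k for k, i in enumerate(nontrain_ids)}
        d = len(self.feature_order)
        posteriors = np.empty((len(nontrain_ids), d))
        for j, name in enumerate(self.feature_order):
            clf = self.classifiers[name]
            X = np.column_stack([self.scores_all[s][nt_rows] for s in clf.segments])
            posteriors[:, j] = clf.posterior_class1(X)
        self.posteriors = posteriors
        self.labels_matrix = (
            np.column_stack(
                [self.binary_all[n].labels[nt_rows] for n in self.feature_order]
            )
            if self.feature_order
            else np.zeros((len(nontrain_ids), 0), dtype=int)
        )
        if (p := self._out("match_posteriors.tsv")) is not None:
            pd.DataFrame(
                posteriors, index=nontrain_ids, columns=self.feature_order
            ).to_csv(p, sep="\t")
        self._done("fuse")

    def _tensor(self, subset_ids) -> np.ndarray:
        """(faces x probes x features) matching scores for given ids."""
        k = np.array([self.nt_pos[i] for i in subset_ids])
        p1 = self.posteriors[k]
        lab = self.labels_matrix[k]
        return np.where(lab[None, :, :] == 1, p1[:, None, :], 1.0 - p1[:, None, :])

    def stage_evaluate(self) -> ExperimentResult:
        """Learned fusion and biometric metrics per rotation, then summary."""
        self._require("evaluate")
        cfg = self.config
        part = self.partition
        group_members: dict[str, list[str]] = {g: [] for g in SUBSET_ORDER}
        for name in self.feature_order:
            group_members[self.deployed[name]["group"]].append(name)
        subsets: dict[str, list[str]] = {}
        acc: list[str] = []
        for gi, g in enumerate(SUBSET_ORDER):
            acc = acc + group_members[g]
            subsets["+".join(gg.upper() for gg in SUBSET_ORDER[: gi + 1])] = list(acc)

        fold_frames = []
        for r, val_ids, test_ids in part.rotations():
            assert not (set(val_ids) & set(test_ids))
            assert not (set(val_ids) | set(test_ids)) & set(part.train_ids)
            df = evaluate_feature_subsets(
                self._tensor(val_ids), self._tensor(test_ids),
                self.feature_order, subsets, prior_mode=cfg.prior_mode,
            )
            df.insert(0, "rotation", r)
            fold_frames.append(df)
        per_fold = pd.concat(fold_frames, ignore_index=True)
        report = (
            per_fold.groupby("subset", sort=False)
            .agg(
                n_features=("n_features", "first"),
                eer=("eer", "mean"), eer_sd=("eer", "std"),
                auc=("auc", "mean"), auc_sd=("auc", "std"),
                r1=("r1", "mean"), r1_sd=("r1", "std"),
                r10=("r10", "mean"), r10_sd=("r10", "std"),
                r20=("r20", "mean"), r20_sd=("r20", "std"),
            )
            .reset_index()
        )
        self.per_fold = per_fold
        self.report = report
        result = ExperimentResult(
            config=cfg,
            partition=part,
            feature_table=self.feature_table,
            feature_fdrd=self.feature_fdrd,
            gwas_table=self.gwas_table,
            gwas_fdrd=self.gwas_fdrd,
            loci=self.loci,
            classifier_inventory=self.classifier_inventory,
            per_fold=per_fold,
            report=report,
            runtime_s=time.time() - self.t0,
        )
        if self.outdir is not None:
            cfg.to_yaml(self.outdir / "config.yaml")
            per_fold.to_csv(self.outdir / "per_fold_metrics.tsv", sep="\t", index=False)
            report.to_csv(self.outdir / "report.tsv", sep="\t", index=False)
            manifest = {
                "seed": cfg.seed,
                "config": asdict(cfg),
                "feature_fdrd": self.feature_fdrd,
                "gwas_fdrd": self.gwas_fdrd,
                "n_classifiers": int(len(self.classifier_inventory)),
                "completed_stages": self.completed,
                "runtime_s": result.runtime_s,
            }
            with open(self.outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
        self._done("evaluate")
        return result


def run_experiment(
    config: ExperimentConfig, outdir=None, cohort: SyntheticCohort | None = None
) -> ExperimentResult:
    """Execute the full face-to-DNA matching experiment in one call."""
    run = PipelineRun(config, outdir=outdir)
    run.stage_simulate(cohort=cohort)
    run.stage_phenotype()
    run.stage_associate()
    run.stage_train()
    run.stage_fuse()
    return run.stage_evaluate()
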