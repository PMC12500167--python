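"""flowgen: flow-based generative modelling of single-cell expression data.

Normalizing flows (a masked autoregressive baseline and a
mixture-of-experts attention flow) for synthesizing cells, third-quartile
class balancing, two-sample fidelity metrics, and a cross-validated
random-forest evaluation pipeline, with a seeded negative-binomial
simulator for test data.
"""

from .balance import (GenerationPlan, fit_per_type, generate_balanced,
                      generate_matched, partition_by_type,
                      proportional_subsample, q3_plan)
from .checkpoint import load_checkpoint, save_checkpoint
from .fixtures import FixtureConfig, simulate_fixture
from .io import (CountMatrix, LabeledDataset, ParseError, PreprocessParams,
                 drop_rare_classes, normalize_log, preprocess_pipeline,
                 qc_filter, read_dataset, read_matrix, select_hvg,
                 write_dataset, write_matrix)
from .maf import (Flow, MAFLayer, base_log_density, build_autoregressive_masks,
                  flow_log_density, nll_loss)
from .metrics import (MetricReport, RBFConfig, batch_silhouette,
                      classification_scores, correlation_discrepancy, mmd_rbf,
                      rmse, wasserstein_mean)
from .moe import (ActNormLayer, ContextMask, MoEConfig, MoECouplingLayer,
                  build_moefb, coupling_split)
from .pipeline import (BenchmarkConfig, BenchmarkResult, FoldSplit,
                       PCAProjection, pc50_project, rf_classify, run_benchmark,
                       stratified_kfold, unique_top_degs)
from .train import FlowDivergenceError, TrainConfig, build_maf, train_flow

__version__ = "0.1.0"

__all__ = [
    "GenerationPlan", "fit_per_type", "generate_balanced", "generate_matched",
    "partition_by_type", "proportional_subsample", "q3_plan",
    "load_checkpoint", "save_checkpoint",
    "FixtureConfig", "simulate_fixture",
    "CountMatrix", "LabeledDataset", "ParseError", "PreprocessParams",
    "drop_rare_classes", "normalize_log", "preprocess_pipeline", "qc_filter",
    "read_dataset", "read_matrix", "select_hvg", "write_dataset", "write_matrix",
    "Flow", "MAFLayer", "base_log_density", "build_autoregressive_masks",
    "flow_log_density", "nll_loss",
    "MetricReport", "RBFConfig", "batch_silhouette", "classification_scores",
    "correlation_discrepancy", "mmd_rbf", "rmse", "wasserstein_mean",
    "ActNormLayer", "ContextMask", "MoEConfig", "MoECouplingLayer",
    "build_moefb", "coupling_split",
    "BenchmarkConfig", "BenchmarkResult", "FoldSplit", "PCAProjection",
    "pc50_project", "rf_classify", "run_benchmark", "stratified_kfold",
    "unique_top_degs",
    "FlowDivergenceError", "TrainConfig", "build_maf", "train_flow",
]
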