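"""Shared fixtures: phantoms, an overfit segmentation network, cohort tables.

Heavy artifacts (trained network, 67-subject cohort, per-arm feature tables)
are session-scoped so the expensive stages run once for the whole suite.
"""

import numpy as np
import pytest

from pdstriatum.analysis import FeatureTable
from pdstriatum.phantom import (
    PhantomConfig,
    build_pet_template,
    generate_cohort,
    generate_subject,
    segmentation_phantom_config,
)
from pdstriatum.pipeline import PipelineConfig, cohort_features
from pdstriatum.segmentation import (
    LossConfig,
    SegNetConfig,
    build_network,
    evaluate_dsc,
    predict,
    train,
    train_to_convergence,
)

SEED = 20240901


@pytest.fixture(scope="session")
def noise_free_config() -> PhantomConfig:
    return PhantomConfig(noise_sd=0.0, geometry_jitter_sd=0.0, seed=SEED)


@pytest.fixture(scope="session")
def noise_free_subject(noise_free_config):
    return generate_subject(noise_free_config, "NL", "unit_nl")


@pytest.fixture(scope="session")
def overfit():
    """Tiny deeply supervised network overfit to one noise-free 32^3 phantom
    (the memorizable-instance convergence check); shared by the smoke tests."""
    cfg = segmentation_phantom_config(noise_sd=0.0, geometry_jitter_sd=0.0, seed=SEED)
    subj = generate_subject(cfg, "NL", "overfit")
    net_cfg = SegNetConfig(input_roi=(32, 32, 32))
    net = build_network(net_cfg, seed=SEED)
    net, traj, _ = train_to_convergence(net, [subj], net_cfg, LossConfig(), seed=SEED)
    pred = predict(net, subj.mr)
    return {
        "net": net,
        "net_cfg": net_cfg,
        "subject": subj,
        "trajectory": traj,
        "dice": evaluate_dsc(pred, subj.labels_mr_space),
    }


@pytest.fixture(scope="session")
def cohort():
    """49 PD / 18 NL phantom cohort under the default study conditions."""
    return generate_cohort(PhantomConfig(), 49, 18, seed=SEED)


@pytest.fixture(scope="session")
def cohort_net(cohort):
    """Segmentation network trained on held-out phantoms drawn from the same
    study conditions as the cohort (training subjects are not cohort members)."""
    cfg = PhantomConfig(seed=SEED + 777)
    train_subjects = [generate_subject(cfg, g, f"segtrain_{i}")
                      for i, g in enumerate(["NL", "PD", "NL"])]
    net_cfg = SegNetConfig(input_roi=(32, 32, 32))
    net = build_network(net_cfg, seed=SEED)
    net, _, dice = train_to_convergence(
        net, train_subjects, net_cfg, LossConfig(), seed=SEED,
        warmup_epochs=20, refine_epochs=20, target_dice=0.85, augment=True)
    return net


@pytest.fixture(scope="session")
def arm_tables(cohort, cohort_net) -> dict[str, FeatureTable]:
    """Feature tables of the three arms on the shared cohort."""
    manual = PipelineConfig(arm="manual_labels", seed=SEED)
    auto = PipelineConfig(arm="multi_modality", seed=SEED, network=cohort_net)
    tmpl, tmpl_labels = build_pet_template(PhantomConfig())
    single = PipelineConfig(arm="single_modality_template", seed=SEED,
                            template=tmpl, template_labels=tmpl_labels)
    tables = {}
    for name, cfg in (("manual", manual), ("auto", auto), ("template", single)):
        table, failures = cohort_features(cohort, cfg)
        assert not failures, f"{name} arm had per-subject failures: {failures}"
        tables[name] = table
    return tables
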