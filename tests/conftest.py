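import pytest
from hypothesis import HealthCheck, settings

import targetrank as tr

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_projects():
    """Two-phenotype synthetic study, 200 genes, strong planted signal."""
    cfg = tr.FixtureConfig(n_genes=200, n_samples=10, n_phenotypes=2,
                           n_planted=5, seed=7)
    bundles = tr.build_projects(cfg)
    projects = [
        tr.Project(matrix=tr.build_feature_matrix(b.dataset, b.snapshots),
                   labels=b.labels)
        for b in bundles
    ]
    return bundles, projects


@pytest.fixture(scope="session")
def small_matrix(small_projects):
    return small_projects[1][0].matrix


def brute_force_ap(ranking, positives, negatives=(), mode="full"):
    """Independent average-precision oracle: walk the ranking and count.

    Enumerates ranks one by one, tracking how many relevant genes have
    been seen, exactly as the precision-at-positive definition reads.
    """
    positives = {g.upper() for g in positives}
    negatives = {g.upper() for g in negatives}
    genes = [g.upper() for g in ranking]
    if mode == "labeled_only":
        genes = [g for g in genes if g in positives or g in negatives]
    precisions = []
    seen_pos = 0
    for rank, gene in enumerate(genes, start=1):
        if gene in positives:
            seen_pos += 1
            precisions.append(seen_pos / rank)
    return sum(precisions) / len(positives)
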