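"""Synthetic multi-cohort expression data and planted weighted bipartite networks.

The generator plants a latent-factor module structure: genes assigned to the
same module share a per-sample factor, so within-module pairs show positive
rank correlation while cross-module pairs correlate only weakly.  Expression
is log-normal-style (Gaussian in log space, exponentiated) to mimic the
positivity and skew of FPKM values; rank-based statistics downstream only see
the monotone structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, ExpressionMatrix, WeightMatrix

UNASSIGNED = "unassigned"


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic multi-cohort bundle.

    ``within_module_loading`` must exceed ``cross_module_loading`` so the
    planted structure is detectable by construction.
    """

    n_cohorts: int = 13
    n_samples_per_cohort: int = 200
    n_chaperones: int = 15
    n_clients: int = 90
    n_modules: int = 3
    within_module_loading: float = 0.9
    cross_module_loading: float = 0.05
    frac_unassigned_clients: float = 0.1
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.cross_module_loading <= 1.0
                and 0.0 <= self.within_module_loading <= 1.0):
            raise ConfigurationError("loadings must lie in [0, 1]")
        # the all-zero loading pair (pure independence) is allowed for testing
        if (self.within_module_loading <= self.cross_module_loading
                and not (self.within_module_loading == 0.0
                         and self.cross_module_loading == 0.0)):
            raise ConfigurationError(
                "within_module_loading must exceed cross_module_loading "
                f"({self.within_module_loading} <= {self.cross_module_loading})")
        if self.n_modules > min(self.n_chaperones, self.n_clients):
            raise ConfigurationError(
                f"n_modules ({self.n_modules}) exceeds "
                f"min(n_chaperones, n_clients) = {min(self.n_chaperones, self.n_clients)}")
        if not 0.0 <= self.frac_unassigned_clients <= 1.0:
            raise ConfigurationError("frac_unassigned_clients must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        for name in ("n_cohorts", "n_samples_per_cohort", "n_chaperones",
                     "n_clients", "n_modules"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


@dataclass
class CohortBundle:
    cohorts: list[ExpressionMatrix]
    chaperone_panel: list[str]
    client_panel: list[str]
    truth: dict[str, object]  # gene -> module label (int) or "unassigned"


def _module_labels(config: SyntheticConfig) -> tuple[list[object], list[object]]:
    """Round-robin module labels so every module holds >= 1 chaperone."""
    k = config.n_modules
    chap = [i % k + 1 for i in range(config.n_chaperones)]
    n_unassigned = int(round(config.frac_unassigned_clients * config.n_clients))
    n_assigned = config.n_clients - n_unassigned
    cli: list[object] = [i % k + 1 for i in range(n_assigned)]
    cli += [UNASSIGNED] * n_unassigned
    return chap, cli


def generate_cohort_bundle(config: SyntheticConfig) -> CohortBundle:
    """Generate T cohorts with planted chaperone-client module structure.

    For each cohort and sample one latent factor per module is drawn; an
    assigned gene's log-expression is
    ``w_in * factor[its module] + w_cross * mean(other factors) + noise`` and
    unassigned clients are noise-only.  Deterministic for a given seed: the
    bundle RNG stream is split per cohort by fixed spawn offsets, so the
    result is independent of generation order.
    """
    config.validate()
    chap_mods, cli_mods = _module_labels(config)
    chaperones = [f"CHAP{i + 1:03d}" for i in range(config.n_chaperones)]
    clients = [f"CLIENT{i + 1:04d}" for i in range(config.n_clients)]
    truth: dict[str, object] = {}
    truth.update(zip(chaperones, chap_mods))
    truth.update(zip(clients, cli_mods))

    gene_ids = chaperones + clients
    mods = chap_mods + cli_mods
    k = config.n_modules
    w_in, w_x, sd = (config.within_module_loading, config.cross_module_loading,
                     config.noise_sd)

    cohort_seeds = np.random.SeedSequence(config.seed).spawn(config.n_cohorts)
    cohorts = []
    for t, ss in enumerate(cohort_seeds):
        rng = np.random.default_rng(ss)
        n = config.n_samples_per_cohort
        factors = rng.standard_normal((k, n))
        other_mean = (factors.sum(axis=0, keepdims=True) - factors) / max(k - 1, 1)
        log_expr = rng.normal(0.0, sd, size=(len(gene_ids), n))
        for g, m in enumerate(mods):
            if m is UNASSIGNED or m == UNASSIGNED:
                continue
            log_expr[g] += w_in * factors[m - 1] + w_x * other_mean[m - 1]
        cohorts.append(ExpressionMatrix(
            cohort_id=f"cohort{t + 1:02d}",
            gene_ids=list(gene_ids),
            sample_ids=[f"S{j + 1:04d}" for j in range(n)],
            values=np.exp(log_expr),
        ))
    return CohortBundle(cohorts=cohorts, chaperone_panel=chaperones,
                        client_panel=clients, truth=truth)


def generate_planted_network(n_chaperones: int, n_clients: int, n_modules: int,
                             w_in: float, w_out: float, edge_prob_in: float,
                             edge_prob_out: float, seed: int,
                             ) -> tuple[WeightMatrix, dict[str, object]]:
    """Directly plant a weighted bipartite module structure.

    Within-module cells get weight ~ ``w_in`` (with small multiplicative
    jitter) with probability ``edge_prob_in``; cross-module cells weight
    ~ ``w_out`` with probability ``edge_prob_out``; all other cells are zero.
    The jitter distribution is identical for both cell classes, so setting
    ``w_in == w_out`` and ``edge_prob_in == edge_prob_out`` yields fully
    exchangeable cells (no planted structure).
    """
    if not (w_in >= w_out >= 0):
        raise ConfigurationError(f"need w_in >= w_out >= 0, got {w_in}, {w_out}")
    for p in (edge_prob_in, edge_prob_out):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"edge probability {p} outside [0, 1]")
    if n_modules > min(n_chaperones, n_clients):
        raise ConfigurationError(
            f"n_modules ({n_modules}) exceeds panel sizes "
            f"({n_chaperones} chaperones, {n_clients} clients)")

    rng = np.random.default_rng(seed)
    chap_mod = np.arange(n_chaperones) % n_modules
    cli_mod = np.arange(n_clients) % n_modules
    same = chap_mod[:, None] == cli_mod[None, :]

    present = rng.random((n_chaperones, n_clients)) < np.where(
        same, edge_prob_in, edge_prob_out)
    jitter = rng.uniform(0.9, 1.1, size=(n_chaperones, n_clients))
    w = np.where(same, w_in, w_out) * jitter * present

    chaperones = [f"CHAP{i + 1:03d}" for i in range(n_chaperones)]
    clients = [f"CLIENT{i + 1:04d}" for i in range(n_clients)]
    truth: dict[str, object] = {}
    truth.update({g: int(m) + 1 for g, m in zip(chaperones, chap_mod)})
    truth.update({g: int(m) + 1 for g, m in zip(clients, cli_mod)})
    return WeightMatrix(chaperones, clients, w), truth


def write_bundle(bundle: CohortBundle, outdir) -> dict[str, str]:
    """Write cohorts, panels, and truth labels as plain-text files."""
    from pathlib import Path

    from .core import write_expression_tsv, write_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for expr in bundle.cohorts:
        p = outdir / f"{expr.cohort_id}.tsv"
        write_expression_tsv(expr, p)
        paths[expr.cohort_id] = str(p)
    write_panel(bundle.chaperone_panel, outdir / "chaperones.txt")
    write_panel(bundle.client_panel, outdir / "clients.txt")
    paths["chaperone_panel"] = str(outdir / "chaperones.txt")
    paths["client_panel"] = str(outdir / "clients.txt")
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene\tmodule\n")
        for g in bundle.chaperone_panel + bundle.client_panel:
            fh.write(f"{g}\t{bundle.truth[g]}\n")
    paths["truth"] = str(truth_path)
    return paths
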