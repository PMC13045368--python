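"""Shared fixtures.

The expensive object is the desk-scale two-domain study: one 32x32
conditional diffusion model trained on the synthetic dataset, plus held-out
test images and their bridge translations.  It is built once per session
and computed lazily, so running a single test only pays for what it needs.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
import pytest

from histobridge.conditioning import ConditionBundle
from histobridge.denoiser import DenoiserConfig, build_denoiser
from histobridge.io_utils import from_model_range, to_model_range
from histobridge.schedule import build_noise_schedule
from histobridge.synthetic import generate_dataset, two_domain_spec
from histobridge.training import train_model
from histobridge.translate import make_timestep_plan, translate_batch

# sizes of the desk-scale study (see docs/methods.md)
TRAIN_STEPS = 2000
TRAIN_N_PER_DOMAIN = 64
TRAIN_SEED = 0
DATA_SEED = 11
TEST_SEED = 123
PLAN_STEPS = (100, 100)

TOY_CONFIG = DenoiserConfig(resolution=32, base_channels=16,
                            channel_multipliers=(1, 2, 4), blocks_per_level=1,
                            embedding_dim=64,
                            attention_levels=(False, False, True))


class ToyStudy:
    """Lazily trained/evaluated synthetic two-domain experiment."""

    def __init__(self):
        self.spec = two_domain_spec(resolution=32)
        self.schedule = build_noise_schedule(1000)

    @cached_property
    def model(self):
        ds = generate_dataset(self.spec, TRAIN_N_PER_DOMAIN, seed=DATA_SEED)
        model = build_denoiser(TOY_CONFIG, self.spec.labels,
                               self.spec.gene_names, seed=TRAIN_SEED,
                               expression_genes=self.spec.expression_gene_names)
        train_model(model, self.schedule, to_model_range(ds.images), ds.bundles,
                    steps=TRAIN_STEPS, batch_size=8, lr=2e-3, seed=TRAIN_SEED,
                    log_every=500)
        return model

    @cached_property
    def test_set(self):
        return generate_dataset(self.spec, 24, seed=TEST_SEED)

    @cached_property
    def plan(self):
        return make_timestep_plan(self.schedule.t_total, *PLAN_STEPS)

    def domain_rows(self, domain: str) -> np.ndarray:
        return np.nonzero((self.test_set.truth["domain"] == domain).to_numpy())[0]

    @cached_property
    def translation_a_to_b(self):
        """Held-out domain_a images translated to domain_b (omics kept)."""
        rows = self.domain_rows("domain_a")
        x = to_model_range(self.test_set.images[rows])
        src = [self.test_set.bundles[i] for i in rows]
        trg = [ConditionBundle.make("domain_b", b.genomic.entries,
                                    b.transcriptomic.entries) for b in src]
        out = translate_batch(x, self.model, src, trg, self.schedule, self.plan)
        return rows, from_model_range(out)

    @cached_property
    def roundtrip_errors(self):
        """Mean abs pixel error of same-condition encode/decode by plan size."""
        rows = self.domain_rows("domain_a")[:8]
        x = to_model_range(self.test_set.images[rows])
        bundles = [self.test_set.bundles[i] for i in rows]
        errors = {}
        for n_total in (50, 100, 200):
            plan = make_timestep_plan(self.schedule.t_total,
                                      n_total // 2, n_total - n_total // 2)
            out = translate_batch(x, self.model, bundles, bundles,
                                  self.schedule, plan)
            errors[n_total] = float(np.abs(out - x).mean())
        return errors

    @cached_property
    def genomic_edit(self):
        """Wild-type domain_a images re-decoded with the blob gene mutated."""
        rows = self.domain_rows("domain_a")
        wt = [i for i in rows
              if not self.test_set.truth["mut_GENE_BLOBS"].iloc[i]][:10]
        x = to_model_range(self.test_set.images[wt])
        src = [self.test_set.bundles[i] for i in wt]
        trg = [ConditionBundle.make("domain_a", {"GENE_BLOBS": True},
                                    b.transcriptomic.entries) for b in src]
        out = translate_batch(x, self.model, src, trg, self.schedule, self.plan)
        return np.asarray(wt), from_model_range(out)


@pytest.fixture(scope="session")
def toy_study():
    return ToyStudy()
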