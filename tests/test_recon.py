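"""OSEM reconstruction: subsets, fixed point, likelihood and consistency."""

import numpy as np
import pytest

from luquant import (DigitalPhantom, ProtocolConfig, PSFModel, ReconConfig,
                     ScatterConfig, VoxelGrid, make_subsets, osem_reconstruct,
                     simulate_acquisition, SPECTReconstruction)
from luquant.projector import Projector
from luquant.simulate import ProjectionSet


class TestMakeSubsets:
    def test_64_views_16_subsets(self):
        groups = make_subsets(64, 16)
        assert len(groups) == 16
        assert all(len(g) == 4 for g in groups)
        # within a group, views are a quarter-turn apart (maximal separation)
        for g in groups:
            assert np.all(np.diff(sorted(g)) == 16)

    def test_groups_partition_all_views(self):
        groups = make_subsets(64, 16)
        flat = np.sort(np.concatenate(groups))
        np.testing.assert_array_equal(flat, np.arange(64))

    def test_processing_order_is_bit_reversed(self):
        groups = make_subsets(64, 16)
        first = [g[0] for g in groups[:4]]
        assert first == [0, 8, 4, 12]

    def test_single_subset_degenerate(self):
        (group,) = make_subsets(4, 1)
        np.testing.assert_array_equal(group, [0, 1, 2, 3])

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_subsets(64, 10)


def _matched_setup(small_cylinder, small_protocol, scatter_level=0.05):
    """Noiseless, exactly explainable data: y = P x + s with x known."""
    act, mu = small_cylinder
    psf = PSFModel()
    proj = Projector(mu, small_protocol, psf)
    rng = np.random.default_rng(8)
    x_true = 40.0 * act.values  # zero outside the body, well inside the FOV
    y = np.stack([np.clip(proj.forward(x_true, v), 0, None)
                  for v in range(small_protocol.n_views)])
    s = scatter_level * y.mean() * np.ones_like(y)
    ps = ProjectionSet(y + s, small_protocol.angles_deg, small_protocol.radii(),
                       dwell_s=small_protocol.dwell_s, pixel_mm=4.8)
    return x_true, s, ps, mu, psf, proj


class TestOsem:
    def test_fixed_point_identity(self, small_cylinder, small_protocol):
        x_true, s, ps, mu, psf, proj = _matched_setup(small_cylinder, small_protocol)
        cfg = ReconConfig(n_iterations=1, n_subsets=4, compensation="ARS",
                          scatter_config=ScatterConfig())
        img = osem_reconstruct(ps, mu, small_protocol, psf, cfg,
                               scatter_projections=s, projector=proj,
                               initial_image=x_true)
        sig = x_true > 1e-9 * x_true.max()
        rel = np.abs(img.values[sig] - x_true[sig]) / x_true[sig]
        assert rel.max() < 1e-6

    def test_outputs_nonnegative_for_arbitrary_data(self, small_cylinder,
                                                    small_protocol, rng):
        _, mu = small_cylinder
        y = rng.poisson(5.0, size=(small_protocol.n_views, 32, 16)).astype(float)
        ps = ProjectionSet(y, small_protocol.angles_deg, small_protocol.radii(),
                           dwell_s=20.0, pixel_mm=4.8)
        cfg = ReconConfig(n_iterations=2, n_subsets=4, compensation="AR")
        img = osem_reconstruct(ps, mu, small_protocol, PSFModel(), cfg)
        assert np.all(img.values >= 0.0)
        assert np.all(np.isfinite(img.values))

    def test_loglikelihood_monotone_on_matched_data(self, small_cylinder,
                                                    small_protocol):
        x_true, s, ps, mu, psf, proj = _matched_setup(small_cylinder, small_protocol)
        cfg = ReconConfig(n_iterations=6, n_subsets=4, compensation="ARS",
                          scatter_config=ScatterConfig())
        img = osem_reconstruct(ps, mu, small_protocol, psf, cfg,
                               scatter_projections=s, projector=proj,
                               track_loglikelihood=True)
        ll = np.asarray(img.provenance["loglikelihood"])
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_count_consistency_after_convergence(self, small_cylinder,
                                                 small_protocol):
        x_true, s, ps, mu, psf, proj = _matched_setup(small_cylinder, small_protocol)
        cfg = ReconConfig(n_iterations=10, n_subsets=4, compensation="ARS",
                          scatter_config=ScatterConfig())
        img = osem_reconstruct(ps, mu, small_protocol, psf, cfg,
                               scatter_projections=s, projector=proj)
        fp = np.clip(proj.forward_views(img.values), 0, None) + s
        assert fp.sum() == pytest.approx(ps.counts.sum(), rel=0.01)

    def test_compensation_requires_matching_projector(self, small_cylinder,
                                                      small_protocol):
        _, mu = small_cylinder
        y = np.ones((small_protocol.n_views, 32, 16))
        ps = ProjectionSet(y, small_protocol.angles_deg, small_protocol.radii(),
                           dwell_s=20.0, pixel_mm=4.8)
        with pytest.raises(ValueError, match="PSF"):
            osem_reconstruct(ps, mu, small_protocol, None,
                             ReconConfig(n_iterations=1, n_subsets=4,
                                         compensation="AR"))

    def test_invalid_compensation_rejected(self):
        with pytest.raises(ValueError, match="compensation"):
            ReconConfig(compensation="AS")

    def test_model_results_interface(self, small_cylinder, small_protocol):
        act, mu = small_cylinder
        ph = DigitalPhantom(activity=act, mu=mu, masks={})
        acq = simulate_acquisition(ph, small_protocol, PSFModel(), seed=1)
        res = SPECTReconstruction(
            acq, mu, small_protocol, PSFModel(),
            ReconConfig(n_iterations=2, n_subsets=4, compensation="AR"),
        ).fit()
        assert res.image.compensation == "AR"
        text = res.summary()
        assert "AR" in text and "2 x 4" in text
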