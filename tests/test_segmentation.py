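"""Thresholding, component extraction, the band B, and beta refinement."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventpve as vp
from ventpve.segmentation import DIRECTIONS
from ventpve.types import GaussianParams


def _slice(arr):
    return vp.ImageSlice(pixels=np.asarray(arr, dtype=float))


class TestThresholdCSF:
    def test_constant_image_below_threshold(self):
        mask = vp.threshold_csf(_slice(np.full((4, 4), 10.0)), 25.0)
        assert mask.all()

    def test_pixel_exactly_at_threshold_is_included(self):
        mask = vp.threshold_csf(_slice([[25.0, 26.0, 24.0]] * 3), 25.0)
        assert mask[0, 0] and not mask[0, 1] and mask[0, 2]

    def test_popcount_matches_bruteforce(self, small_phantom):
        t = 24.0
        mask = vp.threshold_csf(small_phantom.slice, t)
        tally = sum(
            1 for v in small_phantom.slice.pixels.ravel() if v <= t
        )
        assert int(mask.sum()) == tally


def _flood_fill(mask, seed):
    """Independent BFS flood fill over 8-connectivity."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    queue = deque([seed])
    out[seed] = True
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not out[rr, cc]:
                    out[rr, cc] = True
                    queue.append((rr, cc))
    return out


class TestExtractComponent:
    def test_seed_selects_one_blob(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        comp = vp.extract_ventricle_component(mask, seed=(1, 1))
        assert comp[1, 1] and not comp[7, 7]

    def test_single_blob_is_identity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:7, 4:7] = True
        assert np.array_equal(vp.extract_ventricle_component(mask, seed=(5, 5)), mask)

    def test_default_strategy_matches_flood_fill_oracle(self, small_phantom):
        mask = vp.threshold_csf(small_phantom.slice, 24.0)
        centroid = (48, 48)  # ventricle center of the 96x96 single-ellipse phantom
        assert mask[centroid]
        oracle = _flood_fill(mask, centroid)
        comp = vp.extract_ventricle_component(mask)
        assert np.array_equal(comp, oracle)

    def test_seed_off_mask_raises(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:7, 4:7] = True
        with pytest.raises(ValueError, match="seed"):
            vp.extract_ventricle_component(mask, seed=(0, 0))

    def test_no_central_component_raises(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:2, 0:2] = True
        with pytest.raises(ValueError, match="central third"):
            vp.extract_ventricle_component(mask)


class TestBoundaryBand:
    def test_square_band_set_algebra(self):
        comp = np.zeros((11, 11), dtype=bool)
        comp[3:8, 3:8] = True
        band = vp.boundary_band(comp)
        # oracle: direct 8-neighborhood set arithmetic
        inner, outer = set(), set()
        for r in range(11):
            for c in range(11):
                nbrs = [
                    (r + dr, c + dc)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0)
                    and 0 <= r + dr < 11
                    and 0 <= c + dc < 11
                ]
                if comp[r, c] and any(not comp[x] for x in nbrs):
                    inner.add((r, c))
                if not comp[r, c] and any(comp[x] for x in nbrs):
                    outer.add((r, c))
        assert len(inner) == 16 and len(outer) == 24
        assert set(zip(*np.nonzero(band.contour))) == inner
        assert set(zip(*np.nonzero(band.outer))) == outer
        assert np.array_equal(band.member, band.contour | band.outer)

    def test_single_pixel_component(self):
        comp = np.zeros((7, 7), dtype=bool)
        comp[3, 3] = True
        band = vp.boundary_band(comp)
        assert band.member.sum() == 9
        assert band.member[2:5, 2:5].all()

    def test_empty_component_raises(self):
        with pytest.raises(ValueError, match="empty"):
            vp.boundary_band(np.zeros((5, 5), dtype=bool))

    def test_edge_touching_component_raises(self):
        comp = np.zeros((5, 5), dtype=bool)
        comp[0:2, 2] = True
        with pytest.raises(ValueError, match="edge"):
            vp.boundary_band(comp)


class TestBetaShare:
    def test_midpoint_triple(self):
        assert vp.beta_share(10, 20, 30, t_pve=15, p_is_csf_in_b=True) == 0.5

    def test_q_at_or_below_threshold_gives_zero(self):
        assert vp.beta_share(10, 15, 30, t_pve=15, p_is_csf_in_b=True) == 0.0

    def test_r_at_or_below_threshold_gives_zero(self):
        assert vp.beta_share(10, 20, 14, t_pve=15, p_is_csf_in_b=True) == 0.0

    def test_p_not_csf_gives_zero(self):
        assert vp.beta_share(10, 20, 30, t_pve=15, p_is_csf_in_b=False) == 0.0

    def test_q_equal_r_carries_no_share(self):
        assert vp.beta_share(10, 30, 30, t_pve=15, p_is_csf_in_b=True) == 0.0

    def test_degenerate_triple_returns_zero(self):
        assert vp.beta_share(30, 31, 30, t_pve=15, p_is_csf_in_b=True) == 0.0

    def test_clamped_to_unit_interval(self):
        assert vp.beta_share(10, 16, 30, t_pve=15, p_is_csf_in_b=True) <= 1.0
        assert vp.beta_share(10, 40, 30, t_pve=15, p_is_csf_in_b=True) == 0.0

    @given(
        gp=st.integers(0, 20),
        gq=st.integers(21, 60),
        gr=st.integers(21, 60),
        shift=st.integers(-500, 500),
    )
    @settings(derandomize=True, max_examples=100)
    def test_invariant_under_common_affine_shift(self, gp, gq, gr, shift):
        t = 20
        base = vp.beta_share(gp, gq, gr, t, True)
        shifted = vp.beta_share(gp + shift, gq + shift, gr + shift, t + shift, True)
        assert base == pytest.approx(shifted)


WGM = GaussianParams(40.0, 5.0)


class TestImageForce:
    def test_zero_outside_band(self):
        assert vp.image_force(40.0, in_b=False, beta=0.9, alpha0=0.5, wgm=WGM) == 0.0

    def test_peak_of_gaussian_gives_alpha0(self):
        assert vp.image_force(WGM.mu, True, 0.0, 0.6, WGM) == pytest.approx(0.6)

    def test_beta_branch_wins(self):
        got = vp.image_force(WGM.mu + WGM.sigma, True, 0.7, 0.6, WGM)
        assert got == pytest.approx(max(0.6 * np.exp(-0.5), 0.7)) == pytest.approx(0.7)

    def test_gaussian_branch_wins(self):
        got = vp.image_force(WGM.mu + WGM.sigma, True, 0.1, 0.6, WGM)
        assert got == pytest.approx(0.6 * np.exp(-0.5))

    @given(
        x=st.floats(-100, 200),
        beta=st.floats(0, 1),
        alpha0=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=100)
    def test_force_in_unit_interval(self, x, beta, alpha0):
        assert 0.0 <= vp.image_force(x, True, beta, alpha0, WGM) <= 1.0


def _oracle_refine(px, comp, t, alpha0):
    """Exhaustive independent re-derivation of the beta >= alpha0 decision."""
    h, w = px.shape
    # band outer layer: non-component pixels 8-adjacent to the component
    refined = comp.copy()
    for r in range(h):
        for c in range(w):
            if comp[r, c]:
                continue
            adjacent = any(
                0 <= r + dr < h and 0 <= c + dc < w and comp[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
            )
            if not adjacent:
                continue
            best = 0.0
            for dr, dc in DIRECTIONS:
                pr, pc, rr, rc = r + dr, c + dc, r - dr, c - dc
                if not (0 <= pr < h and 0 <= pc < w and 0 <= rr < h and 0 <= rc < w):
                    continue
                if not comp[pr, pc]:
                    continue
                gq, gr_, gp = px[r, c], px[rr, rc], px[pr, pc]
                if gq <= t or gr_ <= t or gr_ == gp:
                    continue
                best = max(best, min(max((gr_ - gq) / (gr_ - gp), 0.0), 1.0))
            if best >= alpha0:
                refined[r, c] = True
    return refined


class TestRefineBoundary:
    def _component(self, phantom, t):
        mask = vp.threshold_csf(phantom.slice, t)
        h, w = mask.shape
        return vp.extract_ventricle_component(mask, seed=(h // 2, w // 2))

    def test_analytic_triple_accepted(self):
        px = np.full((7, 7), 30.0)
        px[2:5, 2:5] = 10.0
        px[1, 3] = 14.0  # beta = (30 - 14) / (30 - 10) = 0.8
        image = _slice(px)
        comp = vp.threshold_csf(image, 12.0)
        res = vp.refine_boundary(image, comp, 12.0, 0.5, WGM)
        assert res.refined[1, 3]
        assert res.refined.sum() == comp.sum() + 1
        dec = {d.pixel: d for d in res.decisions}
        assert dec[(1, 3)].beta == pytest.approx(0.8)
        assert dec[(1, 3)].accepted

    def test_no_growth_when_band_is_pure_background(self):
        px = np.full((9, 9), 30.0)
        px[3:6, 3:6] = 10.0
        image = _slice(px)
        comp = vp.threshold_csf(image, 15.0)
        res = vp.refine_boundary(image, comp, 15.0, 0.5, WGM)
        assert np.array_equal(res.refined, comp)

    def test_monotone_and_confined_to_band(self, small_phantom):
        t = 24.0
        comp = self._component(small_phantom, t)
        res = vp.refine_boundary(small_phantom.slice, comp, t, 0.5, WGM)
        assert np.all(comp <= res.refined)
        assert np.all(res.refined <= (comp | res.band.member))

    def test_matches_exhaustive_oracle(self, small_phantom):
        t = 24.0
        comp = self._component(small_phantom, t)
        res = vp.refine_boundary(small_phantom.slice, comp, t, 0.5, WGM)
        oracle = _oracle_refine(small_phantom.slice.pixels, comp, t, 0.5)
        assert np.array_equal(res.refined, oracle)

    def test_force_field_zero_outside_band(self, small_phantom):
        t = 24.0
        comp = self._component(small_phantom, t)
        res = vp.refine_boundary(small_phantom.slice, comp, t, 0.5, WGM)
        assert np.all(res.force_field[~res.band.member] == 0.0)
        assert np.all((res.force_field >= 0) & (res.force_field <= 1))

    def test_border_decision_agrees_with_generative_label(self):
        # low-noise phantom: the beta >= alpha0 decision should agree with
        # the generative alpha >= alpha0 label on >= 90% of border pixels
        spec = vp.PhantomSpec(
            csf=GaussianParams(10.0, 1.0),
            wgm=GaussianParams(38.0, 1.0),
            seed=21,
        )
        out = vp.generate_phantom(spec)
        assert out.n_border_pixels >= 500
        alpha0 = 0.5
        t = vp.pve_distribution(spec.csf, spec.wgm, alpha0).mu
        mask = vp.threshold_csf(out.slice, t)
        pred = np.zeros_like(mask)
        h, w = mask.shape
        for seed in [(h // 2, w // 2 - w // 8), (h // 2, w // 2 + w // 8)]:
            comp = vp.extract_ventricle_component(mask, seed=seed)
            pred |= vp.refine_boundary(out.slice, comp, t, alpha0, spec.wgm).refined
        border = out.border_mask
        label = out.border_alpha >= alpha0
        agreement = np.mean(pred[border] == label[border])
        assert agreement >= 0.9
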