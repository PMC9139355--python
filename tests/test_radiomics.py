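"""Radiomics: preprocessing, feature inventories, brute-force oracles.

The texture matrices are checked against independent brute-force
enumerations (explicit pair/run/zone/neighborhood counting in plain
Python) on small images.
"""

import itertools

import numpy as np
import pytest

from phymri.constants import MAP_SPECS
from phymri.radiomics import (DiscretizationSpec, discretize,
                              extract_feature_table, extract_features,
                              feature_count, first_order_features,
                              log_filter, resample_isotropic, shape_features,
                              texture_features, znormalize)
from phymri.radiomics.texture import (DIRECTIONS_3D, glcm_matrices,
                                      gldm_matrix, glrlm_matrices,
                                      glszm_matrix, ngtdm_table)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation kernels)


def brute_glcm(levels, ng, offset):
    P = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    for x, y, z in itertools.product(range(nx), range(ny), range(nz)):
        i = levels[x, y, z]
        if i == 0:
            continue
        for sign in (+1, -1):
            x2, y2, z2 = (x + sign * offset[0], y + sign * offset[1],
                          z + sign * offset[2])
            if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                j = levels[x2, y2, z2]
                if j > 0:
                    P[i - 1, j - 1] += 1
    return P


def brute_runs(levels, ng, offset):
    """All maximal same-level runs along one direction."""
    runs = []
    nx, ny, nz = levels.shape
    for x, y, z in itertools.product(range(nx), range(ny), range(nz)):
        i = levels[x, y, z]
        if i == 0:
            continue
        px, py, pz = x - offset[0], y - offset[1], z - offset[2]
        if (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                and levels[px, py, pz] == i):
            continue
        length = 1
        cx, cy, cz = x + offset[0], y + offset[1], z + offset[2]
        while (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz
               and levels[cx, cy, cz] == i):
            length += 1
            cx, cy, cz = cx + offset[0], cy + offset[1], cz + offset[2]
        runs.append((i, length))
    return runs


def brute_zones(levels):
    """Flood-fill 26-connected equal-level zones."""
    zones = []
    visited = np.zeros(levels.shape, bool)
    nx, ny, nz = levels.shape
    for start in itertools.product(range(nx), range(ny), range(nz)):
        if visited[start] or levels[start] == 0:
            continue
        lvl = levels[start]
        stack, size = [start], 0
        visited[start] = True
        while stack:
            cx, cy, cz = stack.pop()
            size += 1
            for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                nxt = (cx + dx, cy + dy, cz + dz)
                if (0 <= nxt[0] < nx and 0 <= nxt[1] < ny and 0 <= nxt[2] < nz
                        and not visited[nxt] and levels[nxt] == lvl):
                    visited[nxt] = True
                    stack.append(nxt)
        zones.append((int(lvl), size))
    return zones


def brute_gldm(levels, ng, alpha=0):
    out = {}
    nx, ny, nz = levels.shape
    for x, y, z in itertools.product(range(nx), range(ny), range(nz)):
        i = levels[x, y, z]
        if i == 0:
            continue
        dep = 1
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
            if (dx, dy, dz) == (0, 0, 0):
                continue
            n = (x + dx, y + dy, z + dz)
            if (0 <= n[0] < nx and 0 <= n[1] < ny and 0 <= n[2] < nz
                    and levels[n] > 0 and abs(int(levels[n]) - int(i)) <= alpha):
                dep += 1
        out[(i, dep)] = out.get((i, dep), 0) + 1
    return out


def brute_ngtdm(levels, ng):
    s = np.zeros(ng)
    n = np.zeros(ng)
    nx, ny, nz = levels.shape
    for x, y, z in itertools.product(range(nx), range(ny), range(nz)):
        i = levels[x, y, z]
        if i == 0:
            continue
        vals = []
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
            if (dx, dy, dz) == (0, 0, 0):
                continue
            nb = (x + dx, y + dy, z + dz)
            if (0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz
                    and levels[nb] > 0):
                vals.append(levels[nb])
        if vals:
            s[i - 1] += abs(i - np.mean(vals))
            n[i - 1] += 1
    return s, n


@pytest.fixture(params=[0, 1, 2])
def random_levels(request):
    rng = np.random.default_rng(request.param)
    lv = rng.integers(0, 5, size=(4, 4, 2)).astype(np.int32)
    if not (lv > 0).any():
        lv[0, 0, 0] = 1
    return lv


class TestTextureMatricesAgainstBruteForce:
    def test_glcm_all_directions(self, random_levels):
        ng = 4
        mats = glcm_matrices(random_levels, ng)
        # kernels crop to the nonzero bounding box; mirror that here
        nz = np.nonzero(random_levels)
        cropped = random_levels[tuple(slice(a.min(), a.max() + 1) for a in nz)]
        for d, offset in enumerate(DIRECTIONS_3D):
            assert np.array_equal(mats[d], brute_glcm(cropped, ng, offset))

    def test_glrlm_all_directions(self, random_levels):
        ng = 4
        mats = glrlm_matrices(random_levels, ng)
        nz = np.nonzero(random_levels)
        cropped = random_levels[tuple(slice(a.min(), a.max() + 1) for a in nz)]
        for d, offset in enumerate(DIRECTIONS_3D):
            expected = np.zeros_like(mats[d])
            for lvl, length in brute_runs(cropped, ng, offset):
                expected[lvl - 1, length - 1] += 1
            assert np.array_equal(mats[d], expected)

    def test_glszm_zones(self, random_levels):
        ng = 4
        P = glszm_matrix(random_levels, ng)
        expected = np.zeros_like(P)
        nz = np.nonzero(random_levels)
        cropped = random_levels[tuple(slice(a.min(), a.max() + 1) for a in nz)]
        for lvl, size in brute_zones(cropped):
            expected[lvl - 1, size - 1] += 1
        assert np.array_equal(P, expected)

    def test_gldm_dependences(self, random_levels):
        ng = 4
        P = gldm_matrix(random_levels, ng)
        nz = np.nonzero(random_levels)
        cropped = random_levels[tuple(slice(a.min(), a.max() + 1) for a in nz)]
        expected = np.zeros_like(P)
        for (lvl, dep), cnt in brute_gldm(cropped, ng).items():
            expected[lvl - 1, dep - 1] = cnt
        assert np.array_equal(P, expected)

    def test_ngtdm_sums_and_counts(self, random_levels):
        ng = 4
        s, n = ngtdm_table(random_levels, ng)
        nz = np.nonzero(random_levels)
        cropped = random_levels[tuple(slice(a.min(), a.max() + 1) for a in nz)]
        s2, n2 = brute_ngtdm(cropped, ng)
        assert np.allclose(s, s2, atol=1e-10)
        assert np.array_equal(n, n2)

    def test_toy_glcm_feature_from_hand_counts(self):
        # 2×2×1 levels [[1,2],[2,1]]: every in-plane pair is (1,2) or (2,1)
        lv = np.array([[[1], [2]], [[2], [1]]], dtype=np.int32)
        mats = glcm_matrices(lv, 2)
        # axis pairs: (1,2)x2 symmetric; diagonal pairs: (1,1) and (2,2)
        feats = texture_features(lv, 2)
        # hand-computed averages over the 4 nonempty directions: the two
        # axis directions pair only (1,2)/(2,1) (contrast 1, energy 0.5),
        # the two in-plane diagonals pair equal levels (contrast 0, energy 1)
        assert feats["glcm_Contrast"] == pytest.approx((1 + 1 + 0 + 0) / 4)
        assert feats["glcm_JointEnergy"] == pytest.approx((0.5 + 0.5 + 1 + 1) / 4)


class TestTextureFeatureProperties:
    def test_inventory_counts(self, random_levels):
        feats = texture_features(random_levels, 4)
        by_family = {}
        for k in feats:
            by_family.setdefault(k.split("_")[0], []).append(k)
        assert {f: len(v) for f, v in sorted(by_family.items())} == {
            "glcm": 24, "gldm": 14, "glrlm": 16, "glszm": 16, "ngtdm": 5}

    def test_constant_region_degenerate_values(self):
        lv = np.full((4, 4, 2), 3, dtype=np.int32)
        feats = texture_features(lv, 5)
        assert feats["glcm_Contrast"] == 0.0
        assert feats["glcm_Correlation"] == 1.0  # degenerate convention
        assert feats["glszm_ZonePercentage"] == pytest.approx(1.0 / 32)
        assert feats["ngtdm_Contrast"] == 0.0

    def test_level_preserving_relabeling_invariance(self, random_levels):
        # adding a constant shifts gray levels; order statistics like
        # run structure are preserved -> run-length emphasis unchanged
        shifted = np.where(random_levels > 0, random_levels + 2, 0)
        a = texture_features(random_levels, 6)
        b = texture_features(shifted.astype(np.int32), 6)
        for name in ("glrlm_LongRunEmphasis", "glrlm_ShortRunEmphasis",
                     "glszm_LargeAreaEmphasis", "gldm_LargeDependenceEmphasis"):
            assert a[name] == pytest.approx(b[name], rel=1e-12)


class TestPreprocess:
    def test_znormalize_moments_and_idempotence(self, rng):
        img = rng.normal(40, 7, (12, 12, 6))
        out = znormalize(img)
        assert abs(out.mean()) < 1e-9 and abs(out.std() - 1) < 1e-9
        again = znormalize(out)
        assert np.allclose(again, out, atol=1e-12)

    def test_znormalize_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            znormalize(np.full((4, 4, 4), 3.0))

    @pytest.mark.parametrize("vmin,vmax,width,expected", [
        (0.0, 3.0, 0.05, 60),      # diffusion map
        (0.0, 500.0, 8.0, 63),     # vessel size map
        (0.0, 1.0, 0.3, 4),        # ceil(3.33)
        (0.0, 100.0, 1.5, 67),     # blood volume map
        (-1000.0, 1000.0, 30.0, 67),
    ])
    def test_bin_counts(self, vmin, vmax, width, expected):
        assert DiscretizationSpec(vmin, vmax, width).n_bins == expected

    def test_map_table_bin_counts(self):
        got = {name: spec.n_bins for name, spec in MAP_SPECS.items()}
        assert got == {"ADC": 60, "CBV": 67, "uCBV": 60, "MVD": 67,
                       "VSI": 63, "MTI": 67, "OEF": 67, "CMRO2": 67,
                       "PO2": 67}

    def test_discretize_level_rule(self):
        spec = DiscretizationSpec(0.0, 3.0, 0.05)
        img = np.array([[[0.0, 0.049, 0.051, 2.999, 5.0, -1.0]]])
        levels, n = discretize(img, spec)
        assert n == 60
        assert levels.tolist() == [[[1, 1, 2, 60, 60, 1]]]

    def test_resample_identity_grid(self, rng):
        img = rng.normal(size=(8, 8, 8))
        out, sp = resample_isotropic(img, (1.0, 1.0, 1.0))
        assert np.allclose(out, img, atol=1e-6) and sp == (1.0, 1.0, 1.0)

    def test_resample_doubles_voxel_count_per_axis(self, rng):
        img = rng.normal(size=(8, 8, 4))
        out, _ = resample_isotropic(img, (2.0, 2.0, 2.0))
        for got, want in zip(out.shape, (16, 16, 8)):
            assert abs(got - want) <= 1
        mask, _ = resample_isotropic(img > 0, (2.0, 2.0, 2.0), is_mask=True)
        assert mask.dtype == bool

    def test_resample_requires_spacing(self, rng):
        with pytest.raises(ValueError, match="spacing"):
            resample_isotropic(rng.normal(size=(4, 4, 4)), None)

    def test_log_filter_properties(self, rng):
        # Laplacian of a constant vanishes up to kernel discretization
        assert np.abs(log_filter(np.full((10, 10, 10), 5.0))).max() < 5e-3
        # centered Gaussian blob: extremum of the response at the center
        x, y, z = np.mgrid[:21, :21, :21] - 10.0
        blob = np.exp(-(x**2 + y**2 + z**2) / (2 * 9.0))
        resp = log_filter(blob, sigma_mm=1.5)
        assert np.unravel_index(np.argmin(resp), resp.shape) == (10, 10, 10)
        # zero-mean kernel: the response nearly cancels over the domain
        assert abs(resp.sum()) < 1e-2 * np.abs(resp).sum()
        with pytest.raises(ValueError, match="sigma"):
            log_filter(blob, sigma_mm=0.0)


class TestShape:
    def test_inventory_and_ball_sphericity(self):
        x, y, z = np.mgrid[:24, :24, :24]
        ball = ((x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2) <= 8**2
        feats = shape_features(ball, (1.0, 1.0, 1.0))
        assert len(feats) == 14
        assert 0.95 < feats["Sphericity"] <= 1.0
        assert feats["VoxelVolume"] == ball.sum()
        assert feats["Maximum3DDiameter"] == pytest.approx(16.0, rel=0.1)

    def test_cube_sphericity_closed_form(self):
        # exact cube, V = L³ and A = 6L²: π^(1/3)·(6V)^(2/3)/A ≈ 0.806
        L = 10.0
        sph = np.pi ** (1 / 3) * (6 * L**3) ** (2 / 3) / (6 * L**2)
        assert sph == pytest.approx(0.806, abs=0.001)
        # the reported sphericity follows the same closed form of the
        # reported mesh volume and surface area
        x, y, z = np.mgrid[:16, :16, :16]
        cube = (x < 10) & (y < 10) & (z < 10)
        feats = shape_features(cube, (1.0, 1.0, 1.0))
        expected = (np.pi ** (1 / 3)
                    * (6 * feats["MeshVolume"]) ** (2 / 3)
                    / feats["SurfaceArea"])
        assert feats["Sphericity"] == pytest.approx(expected, rel=1e-12)

    def test_intensity_invariance(self):
        # shape features never see the image, only the mask
        x, y, z = np.mgrid[:12, :12, :12]
        blob = ((x - 6) ** 2 + (y - 6) ** 2 + (z - 6) ** 2) <= 16
        a = shape_features(blob, (1, 1, 1))
        b = shape_features(blob, (1, 1, 1))
        assert a == b

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shape_features(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestFirstOrder:
    def test_inventory_and_hand_values(self):
        img = np.zeros((2, 1, 1))
        img[0, 0, 0], img[1, 0, 0] = 1.0, 3.0
        mask = np.ones((2, 1, 1), bool)
        feats = first_order_features(img, mask)
        assert len(feats) == 18
        assert feats["Mean"] == 2.0
        assert feats["Range"] == 2.0
        assert feats["Energy"] == 10.0

    def test_constant_region(self):
        img = np.full((3, 3, 1), 5.0)
        feats = first_order_features(img, np.ones((3, 3, 1), bool))
        assert feats["Mean"] == 5.0
        assert feats["Variance"] == 0.0
        assert feats["Entropy"] == 0.0
        assert feats["Uniformity"] == 1.0

    def test_affine_equivariance_of_location_stats(self, rng):
        img = rng.normal(10, 3, (6, 6, 3))
        mask = np.ones(img.shape, bool)
        a = first_order_features(img, mask)
        b = first_order_features(2.0 * img + 5.0, mask)
        for name in ("Mean", "Median", "Minimum", "Maximum"):
            assert b[name] == pytest.approx(2.0 * a[name] + 5.0, rel=1e-12)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            first_order_features(rng.normal(size=(3, 3, 3)),
                                 np.zeros((3, 3, 3), bool))


def _toy_case(rng, label="GBM"):
    shape = (14, 14, 8)
    x, y, z = np.mgrid[:14, :14, :8]
    tumor = ((x - 7) ** 2 + (y - 7) ** 2 + ((z - 4) * 1.5) ** 2) <= 9
    edema = (((x - 7) ** 2 + (y - 7) ** 2 + ((z - 4) * 1.5) ** 2) <= 20) & ~tumor
    images = {}
    for name in ("CET1w", "FLAIR"):
        images[name] = rng.normal(0.0, 1.0, shape)
    for name, spec in MAP_SPECS.items():
        mid = 0.5 * (spec.vmin + spec.vmax)
        width = 0.1 * (spec.vmax - spec.vmin)
        images[name] = np.clip(rng.normal(mid, width, shape),
                               spec.vmin, spec.vmax)
    return {"images": images, "masks": {"tumor": tumor, "edema": edema},
            "spacing": (1.0, 1.0, 1.0), "label": label}


class TestFeatureTable:
    def test_single_image_single_voi_inventory(self, rng):
        case = _toy_case(rng)
        feats = extract_features(case["images"]["ADC"],
                                 case["masks"]["tumor"], (1, 1, 1),
                                 "ADC", "tumor", with_log=False)
        assert len(feats) == 107
        feats_log = extract_features(case["images"]["ADC"],
                                     case["masks"]["tumor"], (1, 1, 1),
                                     "ADC", "tumor", with_log=True)
        assert len(feats_log) == 200

    @pytest.mark.parametrize("data_set,expected", [
        ("cMRI", 800), ("advMRI", 1600), ("phyMRI", 2800),
        ("cMRI+phyMRI", 3600), ("advMRI+phyMRI", 4400),
    ])
    def test_data_set_column_counts(self, rng, data_set, expected):
        table = extract_feature_table([_toy_case(rng)], data_set, vois="both")
        assert table.shape[1] - 1 == expected  # minus the entity column
        assert feature_count(data_set, "both") == expected
        assert not table.drop(columns="entity").isna().any().any()

    def test_missing_modality_named_in_error(self, rng):
        case = _toy_case(rng)
        del case["images"]["FLAIR"]
        with pytest.raises(KeyError, match="FLAIR"):
            extract_feature_table([case], "cMRI")

    def test_column_naming_scheme(self, rng):
        table = extract_feature_table([_toy_case(rng)], "cMRI", vois="tumor")
        assert "CET1w_tumor_orig_shape_Sphericity" in table.columns
        assert "FLAIR_tumor_log_firstorder_Mean" in table.columns
        assert "CET1w_tumor_orig_glcm_Contrast" in table.columns
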