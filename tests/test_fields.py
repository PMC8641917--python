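import numpy as np
import pytest

from glycoadhesion.errors import GeometryError, UndefinedEstimateError
from glycoadhesion.fields import (
    SeparationField,
    compute_patch_grid,
    lateral_correlation,
    local_separations,
    map_bonds_to_patches,
    roughness,
    roughness_series,
    separation_fields,
    separation_histogram,
    smoothed_roughness_series,
)
from glycoadhesion.synthetic import simulate_membrane_pair
from glycoadhesion.trajectory import BoxedFrame, MoleculeSelection, Trajectory


def flat_membrane_frame(z_levels, n_x=4, n_y=4, box=(8.0, 8.0, 15.4), rng=None, jitter=0.0):
    """One membrane: one two-atom lipid per patch per monolayer at given z levels."""
    coords, sels = [], []
    idx = 0
    for li, (leaflet, z) in enumerate(zip(("lower", "upper"), z_levels)):
        for i in range(n_x):
            for j in range(n_y):
                x = (i + 0.5) * box[0] / n_x
                y = (j + 0.5) * box[1] / n_y
                dz = rng.normal(0, jitter) if jitter else 0.0
                coords.append([x, y, z + dz])
                sels.append(
                    MoleculeSelection(
                        f"l{li}_{i}_{j}", "lipid", 1, leaflet,
                        tip_heavy_atoms=np.empty(0, dtype=int),
                        tail_atoms=np.array([idx]),
                        tail_masses=np.array([14.0]),
                    )
                )
                idx += 1
    frame = BoxedFrame(0.0, np.array(coords), np.array(box))
    return frame, sels


def test_flat_membrane_has_uniform_midplane():
    frame, sels = flat_membrane_frame((2.0, 6.0))
    grid = compute_patch_grid(frame, sels, membrane=1, n_x=4, n_y=4)
    assert np.allclose(grid.midplane, 4.0)
    assert grid.patch_side_x == pytest.approx(2.0)
    assert not grid.filled.any()


def test_single_atom_shift_is_local_and_mass_weighted():
    frame, sels = flat_membrane_frame((2.0, 6.0))
    # add a second, heavier tail atom to the molecule in patch (0, 0), upper leaflet
    target = next(s for s in sels if s.molecule_id == "l1_0_0")
    coords = np.vstack([frame.coordinates, [1.0, 1.0, 6.2]])
    target.tail_atoms = np.array([target.tail_atoms[0], len(coords) - 1])
    target.tail_masses = np.array([14.0, 28.0])
    frame2 = BoxedFrame(0.0, coords, frame.box)
    grid = compute_patch_grid(frame2, sels, membrane=1, n_x=4, n_y=4)
    expected_upper = (14.0 * 6.0 + 28.0 * 6.2) / 42.0
    assert grid.monolayer_z[1, 0, 0] == pytest.approx(expected_upper)
    assert grid.midplane[0, 0] == pytest.approx((2.0 + expected_upper) / 2)
    mask = np.ones((4, 4), dtype=bool)
    mask[0, 0] = False
    assert np.allclose(grid.midplane[mask], 4.0)


def test_patch_com_matches_brute_force_oracle(rng):
    frame, sels = flat_membrane_frame((2.0, 6.0), rng=rng, jitter=0.3)
    # scatter x-y too so atoms land in random patches
    frame.coordinates[:, :2] = rng.uniform(0, 8.0, size=(len(frame.coordinates), 2))
    grid = compute_patch_grid(frame, sels, membrane=1, n_x=2, n_y=2)
    for li, leaflet in enumerate(("lower", "upper")):
        for i in range(2):
            for j in range(2):
                num = den = 0.0
                for s in sels:
                    if s.leaflet != leaflet:
                        continue
                    for a, m in zip(s.tail_atoms, s.tail_masses):
                        x, y, z = frame.coordinates[a]
                        if int(x // 4.0) == i and int(y // 4.0) == j:
                            num += m * z
                            den += m
                if den:
                    assert grid.monolayer_z[li, i, j] == pytest.approx(num / den)


def test_empty_patch_filled_by_neighbours(caplog):
    frame, sels = flat_membrane_frame((2.0, 6.0))
    # move the atom of patch (0,0) lower leaflet into patch (1,0)
    frame.coordinates[0, 0] += 2.0
    grid = compute_patch_grid(frame, sels, membrane=1, n_x=4, n_y=4)
    assert grid.filled[0, 0, 0]
    assert grid.monolayer_z[0, 0, 0] == pytest.approx(2.0)


def test_gap_sum_equals_box_height():
    """Flat membranes at 1/4 and 3/4 box height → both gaps are 7.7 nm."""
    f1, s1 = flat_membrane_frame((1.95, 5.75))  # midplane 3.85
    f2, s2 = flat_membrane_frame((9.65, 13.45))  # midplane 11.55
    g1 = compute_patch_grid(f1, s1, membrane=1, n_x=4, n_y=4)
    g2 = compute_patch_grid(f2, s2, membrane=1, n_x=4, n_y=4)
    gaps = local_separations(g1, g2, 15.4)
    assert np.allclose(gaps[0], 7.7)
    assert np.allclose(gaps[1], 7.7)
    assert np.allclose(gaps.sum(axis=0), 15.4)


def test_crossed_membranes_rejected():
    f1, s1 = flat_membrane_frame((1.95, 5.75))
    g1 = compute_patch_grid(f1, s1, membrane=1, n_x=4, n_y=4)
    with pytest.raises(GeometryError):
        local_separations(g1, g1, 15.4)


def field_from_values(values, lz=None):
    values = np.asarray(values, dtype=float)
    lz = np.full(values.shape[0], values[0, 0].mean() * 2 if lz is None else lz)
    return SeparationField(
        l=values, box_heights=lz, patch_side_x=1.5, patch_side_y=1.5
    )


def test_roughness_closed_forms():
    const = field_from_values(np.full((3, 2, 4, 4), 7.7), lz=15.4)
    assert roughness(const).xi_perp == pytest.approx(0.0, abs=1e-12)
    two = np.zeros((1, 2, 1, 2))
    two[0, 0] = [[7.2, 8.2]]
    two[0, 1] = [[8.2, 7.2]]
    est = roughness(field_from_values(two, lz=15.4))
    assert est.l_bar == pytest.approx(7.7)
    assert est.xi_perp == pytest.approx(0.5)
    with pytest.raises(UndefinedEstimateError):
        roughness(field_from_values(np.empty((0, 2, 4, 4)), lz=15.4))


def test_fixed_reference_roughness():
    two = np.zeros((1, 2, 1, 1))
    two[0, 0], two[0, 1] = 8.0, 7.4
    est = roughness(field_from_values(two, lz=15.4), l_bar=7.7)
    assert est.xi_perp == pytest.approx(0.3)


def test_smoothed_series_oracle(rng):
    series = rng.random(200)
    assert np.allclose(smoothed_roughness_series(series, 1), series)
    const = np.full(50, 0.7)
    assert np.allclose(smoothed_roughness_series(const, 50), 0.7)
    smooth = smoothed_roughness_series(series, 50)
    for i in (0, 10, 100, 199):
        lo, hi = max(0, i - 24), min(200, i + 26)
        assert smooth[i] == pytest.approx(series[lo:hi].mean())


def test_histogram_recovers_planted_gaussian(rng):
    """Moment fit on N(7.72, 0.53) samples recovers both within 1% at n=1e5."""
    samples = rng.normal(7.72, 0.53, size=100_000)
    field = field_from_values(samples.reshape(-1, 2, 10, 10), lz=15.44)
    hist = separation_histogram(field, bin_width=0.05)
    assert hist.gauss_mean == pytest.approx(7.72, rel=0.01)
    assert hist.gauss_sd == pytest.approx(0.53, rel=0.01)
    assert np.sum(hist.density * np.diff(hist.bin_edges)) == pytest.approx(1.0, abs=1e-6)
    refined = separation_histogram(field, bin_width=0.05, refine=True)
    assert refined.gauss_sd == pytest.approx(0.53, rel=0.02)


def test_histogram_moments_match_field_moments(rng):
    field = field_from_values(rng.normal(7.7, 0.5, size=(5, 2, 8, 8)), lz=15.4)
    hist = separation_histogram(field, bin_width=0.01)
    centers, widths = hist.bin_centers, np.diff(hist.bin_edges)
    mean_h = np.sum(hist.density * widths * centers)
    var_h = np.sum(hist.density * widths * (centers - mean_h) ** 2)
    assert mean_h == pytest.approx(field.l.mean(), rel=1e-3)
    assert np.sqrt(var_h) == pytest.approx(field.l.std(), rel=1e-3)


def test_degenerate_histogram_refuses_gaussian_fit():
    field = field_from_values(np.full((2, 2, 2, 2), 7.7), lz=15.4)
    hist = separation_histogram(field)
    assert hist.gauss_sd is None and hist.gauss_mean is None


def test_conditional_histogram_shifts_mean(rng):
    """Bonds planted only where l < 7 pull the conditional mean down."""
    values = rng.normal(7.7, 0.5, size=(20, 2, 8, 8))
    field = field_from_values(values, lz=15.4)
    maps = [values[i] < 7.0 for i in range(20)]
    cond = separation_histogram(field, condition="trans-bond", bond_maps=maps)
    full = separation_histogram(field)
    assert cond.gauss_mean < full.gauss_mean
    with pytest.raises(UndefinedEstimateError):
        separation_histogram(field, condition="trans-bond",
                             bond_maps=[np.zeros_like(m, dtype=bool) for m in maps])


def test_correlation_normalization_and_white_noise(rng):
    field = field_from_values(rng.normal(7.7, 0.4, size=(50, 2, 16, 16)), lz=15.4)
    corr = lateral_correlation(field)
    assert corr.C[0] == 1.0
    assert corr.variance == pytest.approx(np.var(field.l), rel=1e-12)
    assert np.all(np.abs(corr.C[1:]) < 0.02)  # iid patches decorrelate


def test_correlation_matches_exhaustive_pair_sum():
    """4x4 hand-written field against an explicit periodic pair sum."""
    vals = np.arange(16, dtype=float).reshape(1, 1, 4, 4) ** 1.3
    field = SeparationField(
        l=vals, box_heights=np.array([vals.mean() * 2]),
        patch_side_x=1.0, patch_side_y=1.0,
    )
    corr = lateral_correlation(field)
    d = vals[0, 0] - vals.mean()
    for k in range(3):
        acc = []
        for i in range(4):
            for j in range(4):
                acc.append(d[i, j] * d[(i + k) % 4, j])  # -k roll along x
                acc.append(d[i, j] * d[i, (j + k) % 4])
        expected = np.mean(acc) / np.mean(d**2)
        assert corr.C[k] == pytest.approx(expected, rel=1e-9)


def test_zero_variance_correlation_rejected():
    field = field_from_values(np.full((2, 2, 4, 4), 8.0), lz=16.0)
    with pytest.raises(UndefinedEstimateError):
        lateral_correlation(field)


def test_roughness_series_uses_per_frame_reference():
    vals = np.zeros((2, 2, 1, 2))
    vals[0] = 7.7  # flat frame → zero roughness
    vals[1, 0] = [[7.2, 8.2]]
    vals[1, 1] = [[8.2, 7.2]]
    field = field_from_values(vals, lz=15.4)
    series = roughness_series(field)
    assert series[0] == 0.0
    assert series[1] == pytest.approx(0.5)


def test_bond_maps_from_binding_events():
    traj, sels, _ = simulate_membrane_pair(n_frames=3, seed=0)

    class FakeEvent:
        start_frame, end_frame = 1, 2

    # anchor two membrane pseudo-lipids as stand-in bound partners
    a, b = sels[0].molecule_id, sels[1].molecule_id
    maps = map_bonds_to_patches(
        traj, sels, {"p": [FakeEvent()]}, {"p": (a, b)}, n_gaps=2
    )
    assert not maps[0].any()
    for f in (1, 2):
        marked = np.nonzero(maps[f][0])
        assert len(marked[0]) >= 1  # both anchors may share a patch
    assert map_bonds_to_patches(traj, sels, {}, {})[0].any() == False


def test_separation_fields_single_membrane_equals_box_height():
    f1, s1 = flat_membrane_frame((1.95, 5.75))
    traj = Trajectory(frames=[f1], frame_interval=0.1)
    field = separation_fields(traj, s1, n_x=4, n_y=4)
    assert field.n_gaps == 1
    assert np.allclose(field.l, 15.4)
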