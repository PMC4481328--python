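import json

import numpy as np
import pytest

import texspace as tx
from texspace import _generators as G
from texspace.texgen import (ParamSet, build_dataset, export_height_map,
                             full_default_counts, generate_height_map,
                             model_ids, parameter_sweep, scaled_counts,
                             write_manifest)


@pytest.mark.parametrize("model_id", model_ids())
def test_generator_deterministic_and_normalized(model_id):
    """Same (params, size) twice gives bit-identical grids in [0, 1]."""
    ps = parameter_sweep(model_id, 3, master_seed=5)[1]
    a = generate_height_map(ps, 64)
    b = generate_height_map(ps, 64)
    assert np.array_equal(a.heights, b.heights)
    assert a.heights.shape == (64, 64)
    assert np.isfinite(a.heights).all()
    assert a.heights.min() == 0.0 and a.heights.max() == 1.0


@pytest.mark.parametrize("model_id", model_ids())
def test_sweep_endpoints_produce_distinct_textures(model_id):
    """The two ends of a parameter sweep differ in at least 1% of pixels."""
    lo, hi = parameter_sweep(model_id, 2, master_seed=3)
    # same seed isolates the parameter effect from the seed effect
    hi = ParamSet(model_id, hi.values, lo.seed)
    spec = tx.MODEL_REGISTRY[model_id]
    size = 64
    if spec.min_size is not None:
        size = max(size, spec.min_size(hi.values))
    a = generate_height_map(lo, size).heights
    b = generate_height_map(hi, size).heights
    assert np.mean(np.abs(a - b) > 1e-9) >= 0.01


def test_parameter_sweep_values():
    sw = parameter_sweep("perlin_noise", 3)
    vals = [p.values["frequency"] for p in sw]
    assert vals == [2.0, 9.0, 16.0]
    mid = parameter_sweep("fractal_fourier", 1)[0]
    assert mid.values["beta"] == pytest.approx((0.5 + 3.0) / 2)
    with pytest.raises(ValueError):
        parameter_sweep("perlin_noise", 0)
    with pytest.raises(ValueError):
        parameter_sweep("no_such_model", 3)


def test_sweep_seeds_are_stable_and_distinct():
    a = parameter_sweep("cellular", 4, master_seed=9)
    b = parameter_sweep("cellular", 4, master_seed=9)
    assert [p.seed for p in a] == [p.seed for p in b]
    assert len({p.seed for p in a}) == 4
    c = parameter_sweep("cellular", 4, master_seed=10)
    assert [p.seed for p in a] != [p.seed for p in c]


def test_paramset_validation():
    with pytest.raises(ValueError):
        ParamSet("perlin_noise", {"frequency": 99.0}, 0)
    with pytest.raises(ValueError):
        ParamSet("perlin_noise", {"bogus": 1.0}, 0)
    with pytest.raises(ValueError):
        ParamSet("no_such_model", {}, 0)


def test_generate_height_map_errors():
    ps = parameter_sweep("perlin_noise", 1)[0]
    with pytest.raises(ValueError):
        generate_height_map(ps, 8)
    big = ParamSet("texton_regular", {"spacing": 64.0, "radius_frac": 0.3}, 1)
    with pytest.raises(ValueError):
        generate_height_map(big, 32)  # stamp spacing exceeds the image


def test_texton_regular_autocorrelation_peaks():
    """Regular-grid textons leave autocorrelation maxima at the spacing."""
    ps = ParamSet("texton_regular", {"spacing": 32.0, "radius_frac": 0.3}, 11)
    h = generate_height_map(ps, 256).heights
    f = np.fft.fft2(h - h.mean())
    ac = np.real(np.fft.ifft2(f * np.conj(f)))
    # the lag-(0,32) and (32,0) values must be local maxima along each axis
    for peak, off in ((ac[0, 32], ac[0, 16]), (ac[32, 0], ac[16, 0]),
                      (ac[0, 32], ac[0, 48]), (ac[32, 0], ac[48, 0])):
        assert peak > off


@pytest.mark.parametrize("step,states", [
    ("forest_fire", {0, 1, 2}),
    ("surface_tension", {0, 1}),
    ("greenberg_hastings", set(range(5))),
])
def test_ca_state_alphabet_closure(step, states):
    """Every cell stays inside the automaton's state alphabet at every step."""
    rng = np.random.default_rng(4)
    if step == "forest_fire":
        s = rng.integers(0, 3, (48, 48))
        for _ in range(30):
            s = G.forest_fire_step(s, 0.05, 0.001, rng)
            assert set(np.unique(s)) <= states
    elif step == "surface_tension":
        s = (rng.random((48, 48)) < 0.5).astype(np.int64)
        for _ in range(10):
            s = G.surface_tension_step(s)
            assert set(np.unique(s)) <= states
    else:
        s = rng.integers(0, 5, (48, 48))
        for _ in range(30):
            s = G.greenberg_hastings_step(s, 5, 1)
            assert set(np.unique(s)) <= states


def test_spectral_synthesis_beta_zero_flat_spectrum():
    """With beta = 0 the radially averaged power spectrum is flat."""
    size = 128
    f = np.fft.fftfreq(size) * size
    fy, fx = np.meshgrid(f, f, indexing="ij")
    r = np.hypot(fy, fx)
    low = (r >= 4) & (r < 12)
    high = (r >= 24) & (r < 48)
    ratios = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        h = G.spectral_synthesis(rng, size, beta=0.0)
        p = np.abs(np.fft.fft2(h)) ** 2
        ratios.append(p[low].mean() / p[high].mean())
    assert 0.8 < np.mean(ratios) < 1.25


def test_build_dataset_order_and_counts():
    ds = build_dataset({"perlin_noise": 5, "cellular": 5}, size=32,
                       with_heights=False)
    assert len(ds) == 10
    assert ds.labels == ["cellular"] * 5 + ["perlin_noise"] * 5  # registry order
    assert len(ds.manifest) == 10
    assert ds.sweep_positions[0] == 0.0 and ds.sweep_positions[4] == 1.0


def test_build_dataset_full_default_450():
    counts = full_default_counts()
    assert sum(counts.values()) == 450 and len(counts) == 23
    ds = build_dataset(counts, with_heights=False)
    assert len(ds) == 450


def test_build_dataset_errors_and_warning():
    with pytest.raises(ValueError):
        build_dataset({}, with_heights=False)
    with pytest.raises(ValueError):
        build_dataset({"perlin_noise": 5}, with_heights=False)
    with pytest.raises(ValueError):
        build_dataset({"perlin_noise": 5, "bogus": 5}, with_heights=False)
    with pytest.warns(UserWarning):
        build_dataset({"perlin_noise": 1, "cellular": 2}, with_heights=False)


def test_scaled_counts_total_and_floor():
    counts = scaled_counts(200)
    assert sum(counts.values()) == 200
    assert set(counts) == set(model_ids())
    assert min(counts.values()) >= 2


def test_dataset_determinism_byte_for_byte(tmp_path):
    cfg = {"perlin_noise": 2, "wavelet_noise": 2}
    outs = []
    for name in ("a", "b"):
        ds = build_dataset(cfg, size=32, master_seed=3)
        p = tmp_path / f"{name}.json"
        write_manifest(ds, p)
        outs.append(p.read_bytes())
        for i, hm in enumerate(ds.samples):
            q = tmp_path / f"{name}{i}.pgm"
            export_height_map(hm, q)
    assert outs[0] == outs[1]
    for i in range(4):
        assert (tmp_path / f"a{i}.pgm").read_bytes() == \
            (tmp_path / f"b{i}.pgm").read_bytes()


def test_height_map_export_roundtrip(tmp_path):
    from PIL import Image
    ps = parameter_sweep("perlin_noise", 1, master_seed=2)[0]
    hm = generate_height_map(ps, 32)
    png = tmp_path / "h.png"
    export_height_map(hm, png)
    back = np.asarray(Image.open(png))
    assert np.array_equal(back, np.round(hm.heights * 65535).astype(np.uint16))
    pgm = tmp_path / "h.pgm"
    export_height_map(hm, pgm)
    txt = pgm.read_text().split()
    assert txt[0] == "P2" and int(txt[1]) == 32 and int(txt[3]) == 65535
    vals = np.array(txt[4:], dtype=np.uint16).reshape(32, 32)
    assert np.array_equal(vals, np.round(hm.heights * 65535).astype(np.uint16))
    with pytest.raises(ValueError):
        export_height_map(hm, tmp_path / "h.tiff")


def test_manifest_json_contents(tmp_path):
    ds = build_dataset({"perlin_noise": 2, "cellular": 2}, size=32,
                       with_heights=False)
    p = tmp_path / "m.json"
    write_manifest(ds, p)
    records = json.loads(p.read_text())
    assert len(records) == 4
    assert records[0]["model_id"] == "cellular"
    assert {"index", "model_id", "parameters", "seed"} <= set(records[0])
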