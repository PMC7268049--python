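"""Generate the synthetic preictal cohort used by the downstream analyses.

Ten hub-coupled epochs (block-linear coupling plus a nonlinear hub on the
focal hippocampus) and six purely linear control epochs, written as HDF5
containers under results/cohort/.  One epoch is additionally exported as
plain EDF to demonstrate the interchange path.
"""

from pathlib import Path

from preictalnet.io import write_epoch_edf, write_epoch_hdf5
from preictalnet.simulate import desk_scale_config, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 2026


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    hub_cfg = desk_scale_config()
    hub_epochs = generate_cohort(hub_cfg, 10, seed=SEED)
    for i, ep in enumerate(hub_epochs):
        write_epoch_hdf5(ep, OUT / f"hub_{i:02d}.h5")
    write_epoch_edf(hub_epochs[0], OUT / "hub_00.edf")

    lin_cfg = desk_scale_config(with_hub=False)
    for i, ep in enumerate(generate_cohort(lin_cfg, 6, seed=SEED + 1)):
        write_epoch_hdf5(ep, OUT / f"linear_{i:02d}.h5")

    print(f"wrote 10 hub epochs + 6 linear control epochs to {OUT}")
    print(f"geometry: {hub_cfg.n_channels} channels, "
          f"{hub_cfg.epoch_duration:.0f} s at {hub_cfg.sampling_rate:.0f} Hz; "
          f"hub on channel HiR01 -> {sorted(hub_cfg.hub_spec.target_channels)}")


if __name__ == "__main__":
    main()
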