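# moanscan

Passive acoustic monitoring of humpback whale (*Megaptera novaeangliae*)
moans in polar coastal waters, built for single-hydrophone observatories
that record year-round under the sea ice. The package covers the full chain
from calibrated audio to ecological summary:

- **Detection** — a spectrogram template of the stereotyped, arch-shaped
  moan (~100 Hz fundamental, ~1.1 s, 240 Hz band) is slid along recording
  spectrograms; zero-mean normalized cross-correlation scores peaks, and
  peaks above a threshold (default 0.42) become timed events with measured
  received levels. A review-export/import round trip mirrors the manual
  verification step: only events marked `true` count downstream.
- **Ranging** — a moored calibration source of known source level and range
  gives an empirical transmission-loss law `TL = a·log10(r)` (r in metres;
  `a = 20` is spherical spreading). Inverting `r = 10^((SL−RL)/a)` with
  one-sd corner perturbations of `RL` and `a` bounds the caller's distance.
- **Presence** — verified detections are binned into daily and monthly
  series against a recording-effort log, and runs of consecutive
  detection-days become bouts.
- **Ice context** — daily ice-concentration grids are queried for the mean
  cover within a great-circle radius of the observatory and joined onto the
  presence series, so calling can be read against ice conditions.
- **Synthetic data** — every input (calibrated audio scenes with scheduled
  moans and exact ground truth, calibration-source receptions, seasonal ice
  grids, seasonal presence years) is generated reproducibly from a seed.

## Worked example

Generate a demo dataset and run the detector:

```sh
$ moanscan generate-fixtures demo --seed 3 --scene-duration 60 --n-calls 3
wrote demo dataset to demo
$ moanscan detect demo/20080101_000000.wav --out events.csv
3 events -> events.csv
```

All three scheduled moans are recovered; `events.csv` holds one row per
event with its correlation score and band-limited received level:

```
time,score,duration_s,band_low_hz,band_high_hz,received_level_db,verified
2008-01-01T00:00:06.641250+00:00,0.8226,1.1,40.0,280.0,97.23,unreviewed
2008-01-01T00:00:14.800500+00:00,0.8177,1.1,40.0,280.0,97.06,unreviewed
2008-01-01T00:00:45.287000+00:00,0.8187,1.1,40.0,280.0,98.00,unreviewed
```

Fit the transmission-loss law to the bundled synthetic reception log
(a moored source at 177 km, 180 dB rms re 1 µPa @ 1 m, received at
70 ± 7 dB) and range a moan received at 86 ± 7 dB assuming a 175 dB source
level:

```sh
$ moanscan fit-tl demo/receptions.csv
TL = 20.86 +- 1.34 * log10(r)   (n = 939)
$ moanscan range -a 20.9 --coefficient-sd 1.3 -s 175 -r 86 --received-level-sd 7
distance 18 km (bounds 5 - 79 km)
```

The fitted coefficient sits near spherical spreading; the corner inversion
says a moan received at 86 dB was produced roughly 18 km away, and no
farther than ~79 km even at the quiet/low-loss corner of the uncertainty
box — which is what motivates summarising ice cover within a 100 km radius.

The same operations are available as a library (`moanscan.detect`,
`moanscan.fit_tl`, `moanscan.estimate_distance`, `moanscan.daily_presence`,
`moanscan.cover_within_radius`, `moanscan.synthdata.*`).

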