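# eegloop

Closed-loop EEG stream processing in pure scientific Python: a
rate-scheduled acyclic graph engine with an in-process publish/subscribe
broker, causal FIR preprocessing (filtering, time-locked and rolling
epoching, baselining, line-noise power), Riemannian covariance
classification (AIRM/log-Euclidean geometry, minimum-distance-to-mean),
an unsupervised odd-one-out detector for oddball paradigms,
stimulus-to-EEG latency calibration from tap artifacts, and session state
machines for two reference applications — all exercised end to end on a
built-in, fully seeded synthetic EEG generator, so no hardware, drivers
or downloads are needed.

## Package layout

| module | contents |
| --- | --- |
| `eegloop.streams` | `StreamInfo`, `SampleBlock`, `MarkerEvent` |
| `eegloop.broker` | topic FIFO publish/subscribe |
| `eegloop.graph` | `GraphSpec` validation (topological order, cycle reporting), node registry, tick scheduler on a simulated clock |
| `eegloop.xdfio` | XDF container read/write and an exact CSV fallback |
| `eegloop.synth` | seeded 1/f + line-noise background, oddball (evoked-response) sessions, motor-imagery sessions with exact covariance targets, tap-calibration sessions — each with a `truth` record |
| `eegloop.preprocess` | windowed-FIR design, stateful causal filtering, epoching, baselining, narrowband power |
| `eegloop.riemann` | SPD geometry, Fréchet means, MDM fit/predict, model persistence |
| `eegloop.oddball` | class representatives, pairwise-distance odd-one-out scores, incremental re-scoring |
| `eegloop.latency` | tap-artifact detection, latency estimation, acoustic/refresh closed forms |
| `eegloop.sessions` | MI and oddball controllers, stimulus schedules, archiving with replay, the reference apps |
| `eegloop.nodes` | graph-node wrappers (`bandpass`, `epoch`, `window`, `oddoneout`, `training`, `inference`, ...) |

## CLI

```bash
# simulated oddball session: streams through the online graph, archives
# raw data + manifest, prints the decision summary
eegloop run --app oddball --seed 1 --out out/oddball-run

# simulated motor-imagery session (calibration -> training -> feedback)
eegloop run --app mi --seed 1

# latency calibration from a recorded tap session (.xdf or archive dir)
eegloop calibrate --input out/tap-session --max-offset 0.5
```

`--config FILE` accepts a YAML document with `synth:`, `oddball:` and
`mi:` sections overriding the corresponding dataclass fields; `--debug`
enables verbose logging.  Archived sessions can be re-processed offline
with `eegloop.sessions.replay_oddball`, which reproduces every online
classification decision bit-identically from the raw archive.

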