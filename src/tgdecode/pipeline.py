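"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` drives: simulate (or load) -> preprocess (baseline
correction, +/-100 uV rejection, common average reference, 2:1 pair
downsampling) -> within-task decoding -> cross-task generalization over the
condition-pair roster and electrode sets (global + six networks) -> cluster
statistics -> peak accuracy/latency tables with network rmANOVA -> ERP
statistics -> machine-readable manifest with content hashes.

A single master seed fans out through named substreams (stage x pair x
network x subject), so re-running any stage with the same config reproduces
it bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import epochs as ep
from .cluster import (ClusterConfig, ClusterResult, bonferroni_adjust,
                      one_sample_cbpt, paired_sensor_cbpt,
                      triangulation_adjacency)
from .decoding import (DecodingConfig, cross_task_generalization,
                       decode_timecourse, peak_accuracy_latency,
                       temporal_generalization)
from .epochs import EpochsSet
from .erp import effects_table, p300_window_mean, paired_t_effect, rm_anova_gg
from .montage import Montage, NetworkMap, default_montage, read_montage_tsv
from .simulate import SimConfig, default_sim_config, simulate_dataset

logger = logging.getLogger("tgdecode")

#: P300 windows per task (ms), closed intervals.
P300_WINDOWS = {"oddball": (250.0, 650.0), "nback": (300.0, 750.0)}

#: The six cross-task condition pairings of the n-back task against the
#: oddball contrast (with-load pairs first, then load-free).
DEFAULT_ROSTER: list[dict] = [
    {"task1": "oddball", "pair1": ("oddball", "standard"),
     "task2": "nback", "pair2": p2}
    for p2 in (
        ("2-back-target", "0-back"),
        ("2-back-nontarget", "0-back"),
        ("3-back-target", "0-back"),
        ("3-back-nontarget", "0-back"),
        ("2-back-target", "2-back-nontarget"),
        ("3-back-target", "3-back-nontarget"),
    )
]

ELECTRODE_SETS = ("global", "frontal", "central", "parietal_occipital",
                  "frontal-central", "frontal-parietal_occipital",
                  "central-parietal_occipital")

ANOVA_NETWORKS = ("frontal", "parietal_occipital",
                  "frontal-parietal_occipital")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: str = "tgdecode_results"
    seed: int = 0
    sim: SimConfig | None = None
    data_dir: str | None = None
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    roster: list[dict] = field(default_factory=lambda: [dict(r) for r in
                                                        DEFAULT_ROSTER])
    networks: tuple[str, ...] = ELECTRODE_SETS
    montage_path: str | None = None
    reject_threshold_uv: float = 100.0
    write_epochs_files: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and self.data_dir is None:
            self.sim = default_sim_config(seed=self.seed)


def run_config_from_yaml(path) -> RunConfig:
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    if "sim" in d and d["sim"] is not None:
        sim = d["sim"]
        if "components" not in sim:
            base = default_sim_config()
            sim.setdefault("components", base.components)
        from .simulate import ComponentSpec, NoiseSpec
        if sim["components"] and isinstance(sim["components"][0], dict):
            sim["components"] = [ComponentSpec(**c) for c in sim["components"]]
        if isinstance(sim.get("noise"), dict):
            sim["noise"] = NoiseSpec(**sim["noise"])
        for key in ("channels", "epoch_window"):
            if key in sim:
                sim[key] = tuple(sim[key])
        d["sim"] = SimConfig(**sim)
    if isinstance(d.get("decoding"), dict):
        d["decoding"] = DecodingConfig(**d["decoding"])
    if isinstance(d.get("cluster"), dict):
        d["cluster"] = ClusterConfig(**d["cluster"])
    if "networks" in d:
        d["networks"] = tuple(d["networks"])
    if "roster" in d:
        d["roster"] = [
            {"task1": r["task1"], "pair1": tuple(r["pair1"]),
             "task2": r["task2"], "pair2": tuple(r["pair2"])}
            for r in d["roster"]]
    return RunConfig(**d)


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _pair_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}".replace("/", "-")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_h5(path: Path, arrays: dict[str, np.ndarray],
              attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr), track_times=False)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def _cluster_table(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cluster": i, "extent": len(c.indices), "mass": c.mass,
             "p": c.p, "significant": c.p < result.alpha}
            for i, c in enumerate(result.clusters)
        ],
        columns=["cluster", "extent", "mass", "p", "significant"],
    )


class Pipeline:
    """Stateful driver so CLI subcommands can run stages independently."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.montage: Montage | None = None
        self.study: dict[str, dict[str, EpochsSet]] | None = None
        self.preprocessed: dict[str, dict[str, EpochsSet]] | None = None
        self.files: list[Path] = []
        self.crosstask_index: dict[str, dict[str, list[str]]] = {}
        self._netmap: NetworkMap | None = None

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        if cfg.montage_path:
            self.montage = read_montage_tsv(cfg.montage_path)
        else:
            self.montage = default_montage()
        if cfg.data_dir is not None:
            self.study = self._load_study(Path(cfg.data_dir))
            logger.info("loaded %d subjects from %s",
                        len(self.study), cfg.data_dir)
            return
        sim = dataclasses.replace(cfg.sim, seed=_derived_seed(cfg.seed, 0))
        self.study = simulate_dataset(sim, self.montage, k=cfg.decoding.k)
        logger.info("simulated %d subjects x %d tasks",
                    len(self.study), len(sim.tasks))
        if cfg.write_epochs_files:
            from .simulate import write_study
            for p in write_study(self.study, self.out / "epochs",
                                 self.montage, sim):
                self.files.append(Path(p))

    @staticmethod
    def _load_study(data_dir: Path) -> dict[str, dict[str, EpochsSet]]:
        study: dict[str, dict[str, EpochsSet]] = {}
        for path in sorted(data_dir.glob("*_epochs.h5")):
            subject, task, _ = path.stem.rsplit("_", 2)
            study.setdefault(subject, {})[task] = ep.read_epochs(path)
        if not study:
            raise FileNotFoundError(f"no *_epochs.h5 files in {data_dir}")
        return study

    def preprocess(self) -> None:
        if self.study is None:
            self.simulate()
        cfg = self.config
        out: dict[str, dict[str, EpochsSet]] = {}
        for subject, tasks in self.study.items():
            out[subject] = {}
            for task, e in tasks.items():
                e = ep.baseline_correct(e)
                e, report = ep.reject_amplitude(e, cfg.reject_threshold_uv)
                if report.n_discarded:
                    logger.warning("%s/%s: discarded %d trials over "
                                   "+/-%g uV", subject, task,
                                   report.n_discarded, cfg.reject_threshold_uv)
                e = ep.common_average_reference(e)
                e = ep.downsample_pairs(e)
                out[subject][task] = e
        self.preprocessed = out
        logger.info("preprocessed %d subjects", len(out))

    def _network_map(self) -> NetworkMap:
        if self._netmap is None:
            self._netmap = NetworkMap.from_montage(self.montage) \
                if self.montage and self.montage.groups else NetworkMap()
        return self._netmap

    def _subset(self, e: EpochsSet, network: str) -> EpochsSet:
        if network == "global":
            return e
        return ep.subset_network(e, self._network_map(), network)

    def _pair_epochs(self, subject: str, task: str, pair: tuple[str, str],
                     network: str) -> tuple[EpochsSet, EpochsSet]:
        e = self._subset(self.preprocessed[subject][task], network)
        out = []
        for cond in pair:
            data = e.select(cond)
            out.append(EpochsSet(
                data=data, times=e.times, sfreq=e.sfreq, channels=e.channels,
                labels=np.full(len(data), cond, dtype=object),
                subject=subject))
        return out[0], out[1]

    def _cluster_config(self, network: str) -> ClusterConfig:
        cfg = self.config.cluster
        alpha = cfg.alpha_out
        if network != "global":
            alpha = bonferroni_adjust(cfg.alpha_out, 6)
        return dataclasses.replace(cfg, test_alpha=alpha,
                                   seed=_derived_seed(self.config.seed, 9))

    def decode_within(self, generalize: bool = False) -> None:
        """Within-task decoding for every distinct roster condition pair."""
        if self.preprocessed is None:
            self.preprocess()
        cfg = self.config
        pairs = []
        for r in cfg.roster:
            for task, pair in ((r["task1"], tuple(r["pair1"])),
                               (r["task2"], tuple(r["pair2"]))):
                if (task, pair) not in pairs:
                    pairs.append((task, pair))
        subjects = sorted(self.preprocessed)
        for p_idx, (task, pair) in enumerate(pairs):
            name = _pair_name(pair)
            for n_idx, network in enumerate(cfg.networks):
                curves, mats, times = [], [], None
                for s_idx, subject in enumerate(subjects):
                    ea, eb = self._pair_epochs(subject, task, pair, network)
                    dcfg = dataclasses.replace(
                        cfg.decoding,
                        seed=_derived_seed(cfg.seed, 2, p_idx, n_idx, s_idx))
                    if generalize and network == "global":
                        res = temporal_generalization(ea, eb, dcfg)
                        mats.append(res.accuracy)
                        curves.append(np.diag(res.accuracy))
                    else:
                        res = decode_timecourse(ea, eb, dcfg)
                        curves.append(res.accuracy)
                    times = res.times
                acc = np.stack(curves)
                cres = one_sample_cbpt(acc, 0.5, self._cluster_config(network))
                stem = f"within_{task}_{name}_{network}"
                tsv = self.out / f"{stem}_timecourse.tsv"
                pd.DataFrame({
                    "time_ms": times,
                    "mean_accuracy": acc.mean(axis=0),
                    "sem": acc.std(axis=0, ddof=1) / np.sqrt(len(acc)),
                    "significant": cres.mask.astype(int),
                }).to_csv(tsv, sep="\t", index=False)
                self.files.append(tsv)
                ctsv = self.out / f"{stem}_clusters.tsv"
                _cluster_table(cres).to_csv(ctsv, sep="\t", index=False)
                self.files.append(ctsv)
                h5 = self.out / f"{stem}.h5"
                arrays = {"accuracy": acc, "times": times,
                          "mask": cres.mask.astype(np.uint8)}
                if mats:
                    arrays["generalization"] = np.stack(mats)
                _write_h5(h5, arrays, {"chance": 0.5, "task": task,
                                       "pair": name, "network": network})
                self.files.append(h5)
                logger.info("within-task %s %s %s done", task, name, network)

    def decode_crosstask(self) -> None:
        if self.preprocessed is None:
            self.preprocess()
        cfg = self.config
        subjects = sorted(self.preprocessed)
        for r_idx, r in enumerate(cfg.roster):
            pair_key = f"{_pair_name(tuple(r['pair1']))}" \
                       f"__{_pair_name(tuple(r['pair2']))}"
            self.crosstask_index.setdefault(pair_key, {})
            net_peaks: dict[str, pd.DataFrame] = {}
            for n_idx, network in enumerate(cfg.networks):
                shared, mats_a, mats_b, res = [], [], [], None
                for s_idx, subject in enumerate(subjects):
                    e1 = self._pair_epochs(subject, r["task1"],
                                           tuple(r["pair1"]), network)
                    e2 = self._pair_epochs(subject, r["task2"],
                                           tuple(r["pair2"]), network)
                    dcfg = dataclasses.replace(
                        cfg.decoding,
                        seed=_derived_seed(cfg.seed, 3, r_idx, n_idx, s_idx))
                    res = cross_task_generalization(e1, e2, dcfg)
                    shared.append(res.shared)
                    mats_a.append(res.matrix_a)
                    mats_b.append(res.matrix_b)
                shared = np.stack(shared)
                cres = one_sample_cbpt(shared, 0.5,
                                       self._cluster_config(network))
                win1 = P300_WINDOWS.get(r["task1"], (250.0, 650.0))
                win2 = P300_WINDOWS.get(r["task2"], (300.0, 750.0))
                peaks = []
                for s_idx, subject in enumerate(subjects):
                    pk = peak_accuracy_latency(
                        shared[s_idx], cres,
                        window=(min(win1[0], win2[0]), max(win1[1], win2[1])),
                        times=res.times_task1, test_times=res.times_task2)
                    peaks.append({
                        "subject": subject, "found": pk.found,
                        "peak_accuracy": pk.accuracy,
                        "train_latency_ms": pk.latency_ms,
                        "test_latency_ms": pk.test_latency_ms,
                    })
                peaks = pd.DataFrame(peaks)
                net_peaks[network] = peaks
                stem = f"crosstask_{pair_key}_{network}"
                files = []
                h5 = self.out / f"{stem}.h5"
                _write_h5(h5, {
                    "matrix_a": np.stack(mats_a), "matrix_b": np.stack(mats_b),
                    "shared": shared, "times_task1": res.times_task1,
                    "times_task2": res.times_task2,
                    "mask": cres.mask.astype(np.uint8),
                }, {"chance": 0.5, "pair": pair_key, "network": network})
                files.append(h5)
                ctsv = self.out / f"{stem}_clusters.tsv"
                _cluster_table(cres).to_csv(ctsv, sep="\t", index=False)
                files.append(ctsv)
                ptsv = self.out / f"{stem}_peaks.tsv"
                peaks.to_csv(ptsv, sep="\t", index=False)
                files.append(ptsv)
                self.files.extend(files)
                self.crosstask_index[pair_key][network] = \
                    [str(f.name) for f in files]
                logger.info("cross-task %s %s done", pair_key, network)
            self._network_anova(pair_key, net_peaks)

    def _network_anova(self, pair_key: str,
                       net_peaks: dict[str, pd.DataFrame]) -> None:
        """rmANOVA of peak accuracy and latency over the three networks."""
        wanted = [n for n in ANOVA_NETWORKS if n in net_peaks]
        if len(wanted) < 2:
            return
        rows = []
        for metric in ("peak_accuracy", "train_latency_ms",
                       "test_latency_ms"):
            cols = {}
            for n in wanted:
                vals = net_peaks[n][metric]
                if vals.isna().any() or not net_peaks[n]["found"].all():
                    cols = None
                    break
                cols[n] = vals.to_numpy(dtype=float)
            if not cols:
                continue
            values = np.column_stack([cols[n] for n in wanted])
            if np.allclose(values.std(axis=0), 0):
                continue
            try:
                res = rm_anova_gg(values, level_names=wanted)
            except ValueError:
                continue
            rows.append({"metric": metric, "F": res.F,
                         "df_num": res.df_num, "df_den": res.df_den,
                         "epsilon": res.epsilon, "p": round(res.p, 3),
                         "partial_eta_sq": res.partial_eta_sq})
            for name, eff in res.posthoc:
                rows.append({"metric": f"{metric} posthoc {name}",
                             "t": eff.t, "p": round(eff.p_bonferroni, 3),
                             "d": eff.d})
        if rows:
            path = self.out / f"crosstask_{pair_key}_network_anova.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            self.files.append(path)

    def erp_stats(self) -> None:
        if self.preprocessed is None:
            self.preprocess()
        subjects = sorted(self.preprocessed)
        rows_means = []
        amp: dict[tuple[str, str], dict[str, float]] = {}
        for subject in subjects:
            for task, e in self.preprocessed[subject].items():
                window = P300_WINDOWS.get(task, (250.0, 650.0))
                if "Pz" not in e.channels:
                    continue
                means = p300_window_mean(e, "Pz", window)
                amp[(subject, task)] = means
                for cond, v in means.items():
                    rows_means.append({"subject": subject, "task": task,
                                       "condition": cond,
                                       "mean_uv": v})
        means_tsv = self.out / "erp_pz_window_means.tsv"
        pd.DataFrame(rows_means).to_csv(means_tsv, sep="\t", index=False)
        self.files.append(means_tsv)

        comparisons = []
        for r in self.config.roster:
            for task, pair in ((r["task1"], tuple(r["pair1"])),
                               (r["task2"], tuple(r["pair2"]))):
                if (task, pair) not in comparisons:
                    comparisons.append((task, pair))
        effect_rows = []
        for task, (c1, c2) in comparisons:
            a = np.array([amp[(s, task)][c1] for s in subjects
                          if (s, task) in amp])
            b = np.array([amp[(s, task)][c2] for s in subjects
                          if (s, task) in amp])
            if len(a) < 2:
                continue
            try:
                eff = paired_t_effect(a, b)
            except ValueError:
                continue
            eff.p_bonferroni = min(1.0, 6 * eff.p)
            effect_rows.append((f"{task}: {c1} vs {c2}", eff))
        ttsv = self.out / "erp_paired_t.tsv"
        effects_table(effect_rows).to_csv(ttsv, sep="\t", index=False)
        self.files.append(ttsv)

        # sensor-space CBPT on the window-mean amplitudes
        if self.montage is not None and len(self.montage.channels) >= 3:
            names, adj = triangulation_adjacency(self.montage)
            clus_rows = []
            for task, (c1, c2) in comparisons:
                e0 = self.preprocessed[subjects[0]][task]
                window = P300_WINDOWS.get(task, (250.0, 650.0))
                per_subj_a, per_subj_b = [], []
                for s in subjects:
                    e = self.preprocessed[s][task]
                    mask = e.time_mask(window)
                    ta = e.select(c1)[:, :, mask].mean(axis=(0, 2))
                    tb = e.select(c2)[:, :, mask].mean(axis=(0, 2))
                    per_subj_a.append(ta)
                    per_subj_b.append(tb)
                order = [e0.channels.index(ch) for ch in names
                         if ch in e0.channels]
                if len(order) != len(names):
                    continue
                a = np.stack(per_subj_a)[:, order]
                b = np.stack(per_subj_b)[:, order]
                ccfg = dataclasses.replace(
                    self.config.cluster, tail="two-sided",
                    seed=_derived_seed(self.config.seed, 8))
                res = paired_sensor_cbpt(a, b, adj, ccfg)
                for i, c in enumerate(res.clusters):
                    clus_rows.append({
                        "comparison": f"{task}: {c1} vs {c2}",
                        "cluster": i,
                        "electrodes": ",".join(names[j] for j in c.indices),
                        "mass": c.mass, "p": c.p,
                        "significant": c.p < res.alpha})
            stsv = self.out / "erp_sensor_clusters.tsv"
            pd.DataFrame(clus_rows, columns=["comparison", "cluster",
                                             "electrodes", "mass", "p",
                                             "significant"]) \
                .to_csv(stsv, sep="\t", index=False)
            self.files.append(stsv)

    def report(self) -> Path:
        manifest = {
            "seed": self.config.seed,
            "n_subjects": len(self.preprocessed or self.study or {}),
            "networks": list(self.config.networks),
            "roster": [
                {"task1": r["task1"], "pair1": list(r["pair1"]),
                 "task2": r["task2"], "pair2": list(r["pair2"])}
                for r in self.config.roster],
            "crosstask": self.crosstask_index,
            "files": {str(p.relative_to(self.out)): _sha256(p)
                      for p in sorted(set(self.files))},
        }
        path = self.out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path


def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] = ("simulate", "preprocess",
                                            "within", "crosstask", "erp",
                                            "report")) -> Path:
    """Run the requested stages and return the manifest path."""
    pipe = Pipeline(config)
    plan = [
        ("simulate", pipe.simulate, "simulate" in stages),
        ("preprocess", pipe.preprocess, "preprocess" in stages),
        ("within", lambda: pipe.decode_within(
            generalize="tga" in stages or "within" in stages),
         "within" in stages or "decode" in stages or "tga" in stages),
        ("crosstask", pipe.decode_crosstask, "crosstask" in stages),
        ("erp", pipe.erp_stats, "erp" in stages),
    ]
    for name, fn, wanted in plan:
        if not wanted:
            continue
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") \
                from err
    return pipe.report()
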