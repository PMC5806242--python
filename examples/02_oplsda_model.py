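"""Fit an OPLS-DA model with cross-validated scores and CV-ANOVA.

The model splits the scaled data into a class-predictive part (scores t)
and class-orthogonal parts (t_o); 7-fold cross-validation, with scaling
refit inside each training fold, yields out-of-fold scores tcv, Q2 and a
CV-ANOVA model p-value.
"""
import chemopls as cp

cfg = cp.SyntheticConfig(n_metabolites=60, seed=1)
_sup, pellet, _truth = cp.generate(cfg)
prepped = cp.preprocess_stratum(pellet)

X = prepped.matrix()
labels = list(prepped.sample_meta["class_label"])

# pellet intensities are strictly positive and roughly log-normal, so the
# model is fitted on log intensities, unit-variance scaled
Xs, params = cp.transform_scale(prepped, mode="unit_variance",
                                log_transform=True)
model = cp.fit_oplsda(Xs, labels, n_pred=1, n_ortho=1, scaling=params)
cv = cp.cross_validate(X, labels, n_pred=1, n_ortho=1, n_folds=7, seed=1,
                       log_transform=True)

print(f"R2X = {model.r2x:.3f}, R2Y = {model.r2y:.3f}  (in-sample fit)")
print(f"Q2  = {cv.q2:.3f}                      (out-of-fold prediction)")
print(f"CV-ANOVA: F = {cv.f:.2f} on ({cv.df1}, {cv.df2}) df, p = {cv.p:.3g}")
mean_pos = cv.tcv[[l == cp.CLASS_POSITIVE for l in labels], 0].mean()
mean_neg = cv.tcv[[l == cp.CLASS_NEGATIVE for l in labels], 0].mean()
print(f"mean tcv[1]: positive class {mean_pos:+.2f}, negative {mean_neg:+.2f}")
print("(opposite-signed cross-validated scores = the classes separate on the "
      "predictive component; p is the probability of such prediction under "
      "no class structure)")
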