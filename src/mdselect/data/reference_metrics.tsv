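dataset	classifier	condition	hamming_score	exact_match	hamming_loss	zero_one_loss
thyroid	J48	before_selection	0.99	0.948	0.01	0.052
thyroid	J48	after_selection	0.978	0.896	0.022	0.104
solar_flare	J48	before_selection	0.912	0.791	0.088	0.209
solar_flare	J48	after_selection	0.912	0.791	0.088	0.209
scene	J48	before_selection	0.849	0.525	0.151	0.475
scene	J48	after_selection	0.75	0.261	0.25	0.739
music	J48	before_selection	0.723	0.213	0.277	0.787
music	J48	after_selection	0.748	0.233	0.252	0.767
yeast	J48	before_selection	0.713	0.142	0.287	0.858
yeast	J48	after_selection	0.725	0.145	0.275	0.855
thyroid	naive_bayes	before_selection	0.946	0.668	0.054	0.332
thyroid	naive_bayes	after_selection	0.967	0.83	0.033	0.17
solar_flare	naive_bayes	before_selection	0.879	0.709	0.121	0.291
solar_flare	naive_bayes	after_selection	0.9	0.782	0.1	0.218
scene	naive_bayes	before_selection	0.862	0.527	0.138	0.473
scene	naive_bayes	after_selection	0.769	0.302	0.231	0.698
music	naive_bayes	before_selection	0.782	0.297	0.218	0.703
music	naive_bayes	after_selection	0.767	0.248	0.233	0.752
yeast	naive_bayes	before_selection	0.713	0.142	0.287	0.858
yeast	naive_bayes	after_selection	0.737	0.127	0.263	0.873
thyroid	svm	before_selection	0.968	0.792	0.032	0.208
thyroid	svm	after_selection	0.967	0.788	0.033	0.212
solar_flare	svm	before_selection	0.912	0.791	0.088	0.209
solar_flare	svm	after_selection	0.912	0.791	0.088	0.209
scene	svm	before_selection	0.91	0.695	0.09	0.305
scene	svm	after_selection	0.774	0.315	0.226	0.685
music	svm	before_selection	0.808	0.356	0.192	0.644
music	svm	after_selection	0.772	0.267	0.228	0.733
yeast	svm	before_selection	0.791	0.251	0.209	0.749
yeast	svm	after_selection	0.769	0.173	0.231	0.827
thyroid	ibk	before_selection	0.973	0.834	0.027	0.166
thyroid	ibk	after_selection	0.969	0.833	0.031	0.167
solar_flare	ibk	before_selection	0.888	0.736	0.112	0.264
solar_flare	ibk	after_selection	0.912	0.791	0.088	0.209
scene	ibk	before_selection	0.886	0.626	0.114	0.374
scene	ibk	after_selection	0.76	0.276	0.24	0.724
music	ibk	before_selection	0.753	0.243	0.247	0.757
music	ibk	after_selection	0.74	0.233	0.252	0.767
yeast	ibk	before_selection	0.762	0.214	0.238	0.786
yeast	ibk	after_selection	0.722	0.123	0.278	0.877
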