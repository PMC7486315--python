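(5.0–)10.0–30.0 cm tall, spreading or rarely erect. Stem papillate throughout, pubescent in lower part, glabrous but with sessile glands in upper part; with 2–3 distinct internodes, the uppermost internode1.5–4.0 cm long and obviously longer than the next upper internode. Basal leaves oblanceolate, glabrous. Cauline leaves linear or lanceolate 10.0–40.0 × 2.0–4.0 mm, glabrous or slightly papillate. Calyx 10.0–14.0 mm long, cylindrical at anthesis and clavate in fruit, glabrous, slightly papillate; teeth unequal; shorter ones 1.0–1.5 mm long, ovate, mucronate; longer ones 1.5–2.0 mm, ovate, acuminate; marginal hairs short (up to 0.5 mm), sparse. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 6.0–7.5 mm long, glabrous; limbs 2.0–3.0 mm long, emarginate or bifid, upper-surface pink, lobes linear, petal limbs cleft to middle or more; coronal scales 0.4–0.5 mm long, ovate, apex entire. Anthophore 4.0–5.0 mm long, glabrous. Anthers exserted; filaments 7.0–8.0 mm long, glabrous. Styles exserted. First pedicel 1.0–3.0 cm in flower, 2.0–3.5 cm in fruit, spreading, glabrous, apex mostly geniculate or antrorse. Capsule 6.0–8.0 mm long, oblong or ellipsoid, fragile, opaque. Seeds 0.5–0.8 mm wide, 0.5–0.7 mm high, testa smooth.
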