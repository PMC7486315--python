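15.0–50.0 cm tall, erect. Stem pubescent in lower part, pubescent in upper part; with 3–5 distinct internodes, the uppermost internode 1.0–10.0 cm long and obviously longer than the next upper internode. Basal leaves oblanceolate 10.0–30.0 × 1.0–6.0 mm, pubescent. Cauline leaves oblanceolate 5.0–40.0 × 2.0–6.0 mm, pubescent. Calyx 12.0–16.0 mm long, campanulate at anthesis and clavate in fruit, glabrous or pubescent; teeth unequal; shorter ones 2.0–3.0 mm, ovate, acuminate; longer ones 2.0–4.0 mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm). Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 7.0–10.0 mm long, glabrous; limbs 5.0–6.0 mm long, divided, upper-surface white or pink, lobes linear, divergent, petal limbs cleft to middle or more; coronal scales 1.3–2.0 mm long, elliptic or obovate, apex slightly dentate. Anthophore 6.5–9.0 mm long, densely tomentose. Anthers exserted; filaments 8.0–12.0 mm long, glabrous. Styles exserted. First pedicel 1.0–3.0 cm in flower, 2.0–5.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 5.5–8.0 mm long, oblong or ellipsoid, fragile, translucent. Seeds 0.5–0.8 mm wide, 0.5–0.7 mm high, testa smooth.
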