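15.0–60.0 cm tall, erect or spreading. Stem pubescent in lower part, scabrous, glabrous but with sessile glands in upper part; with 6–10 distinct internodes, the uppermost internode length 3.0–6.0 cm long and obviously longer than the next upper internode. Basal leaves oblanceolate 30.0–60.0 × 2.0–4.0 mm, pubescent. Cauline leaves linear or lanceolate 10.0–55.0 × 1.0–4.0 mm, pubescent. Calyx 11.0–19.0 mm long, campanulate at anthesis and clavate in fruit, pubescent; teeth unequal; shorter ones 1.5–2.0 mm, ovate, mucronate; longer ones 2.0–2.5 mm, ovate, acuminate; marginal hairs short (up to 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 6.0–7.0 mm long, glabrous; limbs 6.0–8.0 mm long, divided, upper-surface white, lobes linear or oblong, divergent, petal limbs cleft to middle or more, lower-surface green; coronal scales 1.0–2.5 mm long, obovate, apex dentate. Anthophore 8.0–11.0 mm long, densely puberulent. Anthers exserted; filaments 8.0–9.0 mm long, glabrous . Styles exserted. First pedicel 1.0–3.0 cm in flower, 2.0–4.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 5.0–7.0 mm long, ovoid or ellipsoid, fragile, opaque. Seeds 0.7–0.9 mm wide, 0.6–0.7 mm high, testa smooth.
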