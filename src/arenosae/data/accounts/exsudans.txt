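5.0–20.0 cm tall, spreading. Stem pubescent in lower part, scabrous, pubescent with sessile glands in upper part; with 4–7 distinct internodes, the uppermost internode obviously longer than the next upper internode. Basal leaves oblanceolate or spathulate, pubescent. Cauline leaves oblanceolate 10.0–25.0 × 1.0–5.0 mm, pubescent, scabrous. Calyx 7.5–8.5 mm long, campanulate at anthesis and clavate in fruit, pubescent, scabrous; teeth unequal; shorter ones 2.0–3.0 mm, deltoid, acuminate; longer ones 2.0–4.0 mm, deltoid, mucronate; marginal hairs long (longer than 0.5 mm). Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 5.0–6.0 mm long, ciliate; limbs 3.0–4.5 mm long, bifid, upper-surface pink, lobes ovate, petal limbs cleft to less than middle, lower-surface pink; coronal scales ca 0.5 mm long, ovate, apex dentate or erose. Anthophore 3.0–5.0 mm long, densely puberulent. Anthers included; filaments 5.0–6.0 mm long, glabrous or pubescent. Styles exserted. First pedicel 1.0–2.0 cm in flower, 1.0–3.0 cm in fruit,erect, glabrous, apex antrorse. Capsule 5.0–7.0 mm, ellipsoid, fragile, opaque. Seeds 0.7–0.8 mm wide, 0.8–1.0 mm high, testa smooth.
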